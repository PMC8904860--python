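"""Readers and writers for the pipeline's tabular formats.

Coordinates are 1-based inclusive throughout (VCF convention).  All outputs
are plain text: CSV/TSV tables, GMT gene sets, JSON reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .clonal import VariantCall
from .trajectories import GL, CloneTree
from .trial import CaseRecord, MouseSeries, VolumeMeasurement

__all__ = [
    "write_volumes_csv", "read_volumes_csv",
    "write_variants_tsv", "read_variants_tsv",
    "read_gmt",
    "read_dose_matrix_csv", "write_dose_matrix_csv",
    "write_tree_tsv", "read_tree_tsv",
    "read_newick_tree", "read_vcf_variants",
    "write_json",
]


def write_volumes_csv(cases: Sequence[CaseRecord], path: str | Path) -> None:
    rows = []
    for case in cases:
        for s in case.series:
            for m in s.measurements:
                rows.append({"case": case.case_id, "mouse": s.mouse_id,
                             "arm": s.arm, "round": s.round, "day": m.day,
                             "width_mm": m.width, "length_mm": m.length,
                             "early_termination": int(case.early_termination)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_volumes_csv(path: str | Path) -> list[CaseRecord]:
    df = pd.read_csv(path)
    required = {"case", "mouse", "arm", "round", "day", "width_mm", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"volumes CSV missing columns: {sorted(missing)}")
    cases: dict[str, CaseRecord] = {}
    for (case_id, mouse, arm, rnd), grp in df.groupby(["case", "mouse", "arm", "round"]):
        case = cases.setdefault(str(case_id), CaseRecord(case_id=str(case_id)))
        if "early_termination" in df.columns and grp["early_termination"].iloc[0]:
            case.early_termination = True
        ms = MouseSeries(mouse_id=str(mouse), arm=str(arm), round=int(rnd))
        for _, row in grp.sort_values("day").iterrows():
            ms.measurements.append(VolumeMeasurement(
                day=float(row["day"]), width=float(row["width_mm"]),
                length=float(row["length_mm"])))
        case.series.append(ms)
    return [cases[k] for k in sorted(cases)]


_VARIANT_COLS = ["gene", "chrom", "pos", "ref", "alt", "alt_reads", "depth",
                 "cn_tumor", "cn_normal", "purity", "timepoint"]


def write_variants_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_VARIANT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return [VariantCall(gene=str(r.gene), chrom=str(r.chrom), pos=int(r.pos),
                        ref=str(r.ref), alt=str(r.alt),
                        alt_reads=int(r.alt_reads), depth=int(r.depth),
                        cn_tumor=int(r.cn_tumor), cn_normal=int(r.cn_normal),
                        purity=float(r.purity), timepoint=str(r.timepoint))
            for r in df.itertuples()]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, description, genes")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_dose_matrix_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(float)
    df.columns = df.columns.astype(float)
    return df


def write_dose_matrix_csv(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path)


def write_tree_tsv(trees: Sequence[CloneTree], path: str | Path) -> None:
    rows = []
    for t in trees:
        for child, parent in sorted(t.parent.items()):
            rows.append({"case": t.case_id, "timepoint": t.timepoint,
                         "child": child, "parent": parent,
                         "drivers": ";".join(t.drivers.get(child, []))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree_tsv(path: str | Path) -> list[CloneTree]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"case", "timepoint", "child", "parent", "drivers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tree TSV missing columns: {sorted(missing)}")
    trees = []
    for (case, tp), grp in df.groupby(["case", "timepoint"], sort=True):
        parent, drivers = {}, {}
        for _, row in grp.iterrows():
            parent[str(row["child"])] = str(row["parent"])
            if str(row["drivers"]):
                drivers[str(row["child"])] = str(row["drivers"]).split(";")
        trees.append(CloneTree(case_id=str(case), timepoint=str(tp),
                               parent=parent, drivers=drivers))
    return trees


def read_newick_tree(path: str | Path, case_id: str, timepoint: str) -> CloneTree:
    """Newick clone tree; node labels are ``clone`` or ``clone|geneA;geneB``.

    The root is mapped to GL regardless of its label.
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    parent: dict[str, str] = {}
    drivers: dict[str, list[str]] = {}

    def name_of(node) -> str:
        raw = (node.taxon.label if node.taxon else node.label) or ""
        return raw.split("|")[0].strip() or "GL"

    def drivers_of(node) -> list[str]:
        raw = (node.taxon.label if node.taxon else node.label) or ""
        if "|" in raw:
            return [g for g in raw.split("|", 1)[1].split(";") if g]
        return []

    root = tree.seed_node
    mapping = {root: GL}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        name = name_of(node)
        mapping[node] = name
        parent[name] = mapping[node.parent_node]
        dr = drivers_of(node)
        if dr:
            drivers[name] = dr
    return CloneTree(case_id=case_id, timepoint=timepoint,
                     parent=parent, drivers=drivers)


def read_vcf_variants(path: str | Path, timepoint: str = "pre",
                      purity: float = 1.0) -> list[VariantCall]:
    """Single-sample VCF import via cyvcf2 using FORMAT AD/DP for counts.

    Copy number defaults to diploid; supply a per-variant table for CN-aware
    CCFs.  Records without usable depth are skipped and counted in the log.
    """
    from cyvcf2 import VCF

    out = []
    vcf = VCF(str(path))
    for rec in vcf:
        try:
            ad = rec.format("AD")
            depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None \
                else int(ad[0].sum())
            alt_reads = int(ad[0][1])
        except (TypeError, IndexError):
            continue
        if depth <= 0:
            continue
        gene = dict(rec.INFO).get("GENE", rec.ID or f"{rec.CHROM}:{rec.POS}")
        out.append(VariantCall(gene=str(gene), chrom=rec.CHROM, pos=rec.POS,
                               ref=rec.REF, alt=rec.ALT[0] if rec.ALT else "N",
                               alt_reads=alt_reads, depth=depth,
                               purity=purity, timepoint=timepoint))
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
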