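"""Readers and writers for every external file format.

Formats
-------
MAF
    Standard tab-separated Mutation Annotation Format. Both full TCGA-style
    headers and a minimal 3-column toy dialect are accepted; columns are
    matched case-insensitively against a canonical-name alias table.
Pathway file
    Plain-text blocks::

        PATHWAY <id> <name...>
        GENES g1 g2 ...
        EDGE gA gB
        EDGE ...

    separated by blank lines. Isolated genes (declared, no edge) are legal.
Coverage table
    2-column TSV ``gene<TAB>covered_bases``.
Impact table
    TSV ``gene<TAB>sample<TAB>position<TAB>score``; mutations are keyed by
    (gene, sample, position).
Config
    Flat ``key<TAB>value`` (``=`` also accepted) mirroring RunConfig fields.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import fields as dc_fields
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .types import MAF_CLASS_MAP, MutationRecord, PathwayGraph, RunConfig, VariantClass

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# canonical name -> accepted lower-cased header aliases
_MAF_ALIASES = {
    "gene": ("hugo_symbol", "gene", "gene_symbol"),
    "sample": ("tumor_sample_barcode", "sample", "sample_barcode"),
    "variant_class": ("variant_classification", "variant_class", "class"),
    "position": ("start_position", "start", "position"),
    "impact": ("impact", "ma_score", "fi_score"),
    "length": ("length", "bases_mutated"),
}


def _resolve_columns(columns: Iterable[str]) -> Dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canon, aliases in _MAF_ALIASES.items():
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
    return resolved


def read_maf(
    path: str,
    impact_table: Optional[Mapping[Tuple[str, str, str], float]] = None,
) -> List[MutationRecord]:
    """Read a MAF file into a list of :class:`MutationRecord`.

    Variant classifications are collapsed (Silent -> silent,
    Missense_Mutation -> missense, Nonsense_Mutation -> nonsense,
    Frame_Shift_Ins/Del and In_Frame_Ins/Del -> indel, Splice_Site ->
    splice_site, anything else -> other). Rows are kept in file order and
    none are dropped.

    Parameters
    ----------
    path : str
        MAF file path.
    impact_table : mapping, optional
        (gene, sample, position) -> functional impact score; matched rows
        get their ``impact`` field filled. An ``impact`` column in the MAF
        itself takes precedence.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty MAF file") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty MAF file")
    cols = _resolve_columns(df.columns)
    for required in ("gene", "sample", "variant_class"):
        if required not in cols:
            raise FormatError(
                f"{path}: missing mandatory MAF column for '{required}' "
                f"(accepted headers: {', '.join(_MAF_ALIASES[required])})"
            )

    def column(canon):
        return df[cols[canon]].tolist() if canon in cols else [None] * len(df)

    records: List[MutationRecord] = []
    n_unknown_symbol = 0
    n_other = 0
    for gene_v, sample_v, class_v, pos_v, imp_v, len_v in zip(
        column("gene"), column("sample"), column("variant_class"),
        column("position"), column("impact"), column("length"),
    ):
        gene = str(gene_v).strip()
        sample = str(sample_v).strip()
        raw_class = str(class_v).strip()
        vclass = MAF_CLASS_MAP.get(raw_class.lower(), VariantClass.OTHER)
        if vclass is VariantClass.OTHER:
            n_other += 1
        if gene.lower() in ("unknown", ".", "-", "na"):
            n_unknown_symbol += 1
        position = str(pos_v).strip() if pos_v is not None else "0"
        impact = None
        if imp_v is not None and str(imp_v).strip() not in ("", "NA", "nan", "."):
            impact = float(imp_v)
        if impact is None and impact_table is not None:
            impact = impact_table.get((gene, sample, position))
        length = 1
        if len_v is not None and str(len_v).strip() not in ("", "NA", "nan", "."):
            length = max(1, int(float(len_v)))
        records.append(
            MutationRecord(
                gene=gene,
                sample=sample,
                variant_class=vclass,
                position=position,
                impact=impact,
                length=length,
            )
        )
    if n_unknown_symbol:
        log.warning("%s: %d rows with unmappable gene symbols (kept)", path, n_unknown_symbol)
    if n_other:
        log.info(
            "%s: %d rows with variant classes outside the scoring rule "
            "(mapped to 'other'; excluded from impact rows)",
            path,
            n_other,
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str) -> None:
    """Write records as a minimal tab-separated MAF."""
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Tumor_Sample_Barcode": r.sample,
            "Variant_Classification": _maf_class_name(r.variant_class),
            "Start_Position": r.position,
            "Length": r.length,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "Tumor_Sample_Barcode",
            "Variant_Classification",
            "Start_Position",
            "Length",
        ],
    ).to_csv(path, sep="\t", index=False)


def _maf_class_name(vc: VariantClass) -> str:
    return {
        VariantClass.SILENT: "Silent",
        VariantClass.MISSENSE: "Missense_Mutation",
        VariantClass.NONSENSE: "Nonsense_Mutation",
        VariantClass.INDEL: "Frame_Shift_Del",
        VariantClass.SPLICE_SITE: "Splice_Site",
        VariantClass.OTHER: "Other",
    }[vc]


def read_pathways(path: str) -> List[PathwayGraph]:
    """Parse the plain-text pathway dialect into PathwayGraph objects.

    File order is preserved. An EDGE whose endpoint was not declared on the
    block's GENES line is a format error.
    """
    pathways: List[PathwayGraph] = []
    cur_id = cur_name = None
    cur_genes: List[str] = []
    cur_edges: List[Tuple[str, str]] = []

    def flush():
        nonlocal cur_id, cur_name, cur_genes, cur_edges
        if cur_id is None:
            return
        declared = set(cur_genes)
        for a, b in cur_edges:
            if a not in declared or b not in declared:
                raise FormatError(
                    f"{path}: pathway {cur_id}: edge {a}-{b} references an "
                    "undeclared gene"
                )
        pathways.append(PathwayGraph.make(cur_id, cur_name or cur_id, declared, cur_edges))
        cur_id = cur_name = None
        cur_genes, cur_edges = [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                flush()
                continue
            tokens = line.split()
            tag = tokens[0].upper()
            if tag == "PATHWAY":
                flush()
                if len(tokens) < 2:
                    raise FormatError(f"{path}:{lineno}: PATHWAY needs an id")
                cur_id = tokens[1]
                cur_name = " ".join(tokens[2:]) if len(tokens) > 2 else tokens[1]
            elif tag == "GENES":
                if cur_id is None:
                    raise FormatError(f"{path}:{lineno}: GENES outside a PATHWAY block")
                cur_genes.extend(tokens[1:])
            elif tag == "EDGE":
                if cur_id is None:
                    raise FormatError(f"{path}:{lineno}: EDGE outside a PATHWAY block")
                if len(tokens) != 3:
                    raise FormatError(f"{path}:{lineno}: EDGE takes exactly two genes")
                cur_edges.append((tokens[1], tokens[2]))
            else:
                raise FormatError(f"{path}:{lineno}: unknown directive {tokens[0]!r}")
    flush()
    return pathways


def write_pathways(pathways: Iterable[PathwayGraph], path: str) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write(f"PATHWAY {pw.pathway_id} {pw.name}\n")
            fh.write("GENES " + " ".join(sorted(pw.genes)) + "\n")
            for a, b in sorted(pw.edges):
                fh.write(f"EDGE {a} {b}\n")
            fh.write("\n")


def read_coverage(path: str) -> Dict[str, int]:
    """Read the 2-column gene -> covered_bases TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "covered_bases"], dtype=str)
    # tolerate a header row
    if not df.empty and not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    out: Dict[str, int] = {}
    for gene, cov in zip(df["gene"], df["covered_bases"]):
        value = int(cov)
        if value <= 0:
            raise FormatError(f"{path}: covered_bases for {gene} must be > 0")
        out[str(gene)] = value
    return out


def write_coverage(coverage: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for gene in sorted(coverage):
            fh.write(f"{gene}\t{coverage[gene]}\n")


def read_impact_table(path: str) -> Dict[Tuple[str, str, str], float]:
    """Read the (gene, sample, position) -> score TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene", "sample", "position", "score"], dtype=str
    )
    if not df.empty:
        try:
            float(df.iloc[0, 3])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    out: Dict[Tuple[str, str, str], float] = {}
    for g, s, p, sc in zip(df["gene"], df["sample"], df["position"], df["score"]):
        score = float(sc)
        if score < 0:
            raise FormatError(f"{path}: negative impact score for {g}")
        out[(str(g), str(s), str(p))] = score
    return out


def write_impact_table(table: Mapping[Tuple[str, str, str], float], path: str) -> None:
    with open(path, "w") as fh:
        for (g, s, p) in sorted(table):
            fh.write(f"{g}\t{s}\t{p}\t{table[(g, s, p)]!r}\n")


def read_config(path: str) -> RunConfig:
    """Read a flat key-value config file mirroring RunConfig fields."""
    values = {}
    field_types = {f.name: f.type for f in dc_fields(RunConfig)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'key value' or 'key = value'")
                key, val = parts
            key, val = key.strip(), val.strip()
            if key not in field_types:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            caster = float if "float" in str(field_types[key]) or key in (
                "alpha",
                "dominance_delta",
                "collab_p_threshold",
            ) else int
            values[key] = caster(val)
    return RunConfig(**values)


def write_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        for f in dc_fields(RunConfig):
            fh.write(f"{f.name}\t{getattr(cfg, f.name)!r}\n")


# ---------------------------------------------------------------------------
# result tables


def write_results(enrichment, collab, out_dir: str) -> None:
    """Write the enrichment table, the collaborative-set report and a JSON summary.

    ``enrichment`` is a list of EnrichmentResult, ``collab`` a
    CollaborativeSet (see :mod:`mudpac.enrichment` and
    :mod:`mudpac.collaboration`). Files written: ``enrichment.tsv``,
    ``collaboration.tsv``, ``summary.json``; all round-trip through the
    companion readers to machine precision.
    """
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "enrichment.tsv"), "w") as fh:
        fh.write("pathway_id\tmd\tp\tfdr\trank\n")
        for r in enrichment:
            fh.write(f"{r.pathway_id}\t{r.md!r}\t{r.p!r}\t{r.fdr!r}\t{r.rank}\n")
    with open(os.path.join(out_dir, "collaboration.tsv"), "w") as fh:
        fh.write("step\tpathway_id\tmcr_after\tp\tmax_gene_rate\n")
        for i, st in enumerate(collab.steps, 1):
            fh.write(
                f"{i}\t{st.pathway_id}\t{st.mcr_after!r}\t{st.p!r}\t{st.max_gene_rate!r}\n"
            )
    summary = {
        "n_pathways_tested": len(enrichment),
        "selected_pathways": [st.pathway_id for st in collab.steps],
        "mcr": collab.mcr,
        "covered_samples": sorted(collab.covered_samples),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_enrichment_table(path: str):
    from .enrichment import EnrichmentResult

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        EnrichmentResult(
            pathway_id=row.pathway_id,
            md=float(row.md),
            p=float(row.p),
            fdr=float(row.fdr),
            rank=int(row.rank),
        )
        for row in df.itertuples(index=False)
    ]


def read_collaboration_table(path: str):
    from .collaboration import SelectionStep

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SelectionStep(
            pathway_id=row.pathway_id,
            mcr_after=float(row.mcr_after),
            p=float(row.p),
            max_gene_rate=float(row.max_gene_rate),
        )
        for row in df.itertuples(index=False)
    ]
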