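"""Mutation-class filtering, pathway/APM mutant calling and prevalence.

Also hosts the cross-study aggregation helpers used to pick core
immunomodulatory pathways from screen-derived enrichment tables.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "APM_GENES",
    "is_nonsynonymous",
    "apm_mutant_call",
    "prevalence_table",
    "select_top_regulators",
    "enrichment_frequency",
]

logger = logging.getLogger(__name__)

#: Variant classifications counted as non-synonymous.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Missense_Mutation",
    }
)
_NONSYN_LOWER = frozenset(c.lower() for c in NONSYNONYMOUS_CLASSES)

#: Antigen presentation machinery genes evaluated for point mutations.
APM_GENES = frozenset(
    {"B2M", "NLRC5", "PSMB8", "PSMB9", "PSMB10", "ERAP1", "ERAP2", "TAP1", "TAP2", "TAPBP"}
)

_unknown_class_warnings = 0


def unknown_classification_count() -> int:
    """Number of unrecognised variant classifications seen so far."""
    return _unknown_class_warnings


_KNOWN_SYNONYMOUS = {
    "silent",
    "synonymous",
    "3'utr",
    "5'utr",
    "3'flank",
    "5'flank",
    "intron",
    "igr",
    "rna",
    "noncoding",
}


def is_nonsynonymous(classification: str) -> bool:
    """True iff the variant classification is in the non-synonymous list.

    Unknown labels return False and bump a module-level warning counter.
    """
    global _unknown_class_warnings
    label = str(classification).strip().lower()
    if label in _NONSYN_LOWER:
        return True
    if label not in _KNOWN_SYNONYMOUS:
        _unknown_class_warnings += 1
        logger.warning("unknown variant classification %r treated as synonymous", classification)
    return False


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


def apm_mutant_call(
    sample_mutations: pd.DataFrame,
    has_hla_loh: bool,
    apm_genes: Iterable[str] = APM_GENES,
) -> bool:
    """A sample is APM-mutant iff it has HLA LOH or a non-synonymous point
    mutation in an antigen-presentation-machinery gene."""
    if has_hla_loh:
        return True
    if len(sample_mutations) == 0:
        return False
    apm = {_norm_gene(g) for g in apm_genes}
    genes = sample_mutations["gene"].map(_norm_gene)
    nonsyn = sample_mutations["classification"].map(is_nonsynonymous)
    return bool((genes.isin(apm) & nonsyn).any())


def prevalence_table(
    mutations: pd.DataFrame,
    gene_sets: Mapping[str, Iterable[str]],
    sample_types: Optional[Mapping[str, str]] = None,
    all_samples: Optional[Iterable[str]] = None,
    filter_nonsynonymous: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample×pathway mutation-status matrix and prevalence fractions.

    A sample is pathway-mutant iff it carries at least one (by default
    non-synonymous) mutation in the pathway's genes. Duplicate mutation
    rows (same sample, gene, position) collapse to one record first.

    Returns
    -------
    (matrix, prevalence, leftover)
        ``matrix``: boolean DataFrame indexed by sample (the oncoprint
        input). ``prevalence``: mutant fraction per cancer type (row
        "ALL" = overall). ``leftover``: genes mutated but present in no
        gene set, with mutation counts.
    """
    mut = mutations.copy()
    mut["gene"] = mut["gene"].map(_norm_gene)
    if filter_nonsynonymous and len(mut):
        mut = mut[mut["classification"].map(is_nonsynonymous)]
    dedup_cols = [c for c in ("sample", "gene", "chrom", "pos") if c in mut.columns]
    mut = mut.drop_duplicates(subset=dedup_cols)

    samples = sorted(
        set(map(str, all_samples)) if all_samples is not None else set(mut["sample"].astype(str))
    )
    sets_norm = {name: {_norm_gene(g) for g in genes} for name, genes in gene_sets.items()}
    matrix = pd.DataFrame(False, index=samples, columns=sorted(sets_norm))
    matrix.index.name = "sample"
    covered: set[str] = set()
    for name, genes in sets_norm.items():
        covered |= genes
        hit = mut[mut["gene"].isin(genes)]
        matrix.loc[matrix.index.isin(hit["sample"].astype(str).unique()), name] = True

    leftover = (
        mut[~mut["gene"].isin(covered)]
        .groupby("gene")
        .size()
        .rename("n_mutations")
        .reset_index()
        .sort_values(["n_mutations", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )

    rows = [matrix.mean(axis=0).rename("ALL")]
    if sample_types is not None:
        types = pd.Series({s: sample_types.get(s, "unknown") for s in matrix.index})
        for ctype, grp in matrix.groupby(types, sort=True):
            rows.append(grp.mean(axis=0).rename(str(ctype)))
    prevalence = pd.DataFrame(rows)
    prevalence.index.name = "cancer_type"
    return matrix, prevalence, leftover


def select_top_regulators(
    ranked: pd.DataFrame,
    n: int = 100,
    direction: str = "positive",
    gene_col: str = "gene",
    direction_col: str = "direction",
) -> list[str]:
    """First ``n`` genes of the requested regulation direction from a
    ranked screen-hit table (fewer, with a warning, if the table is
    shorter)."""
    if direction_col not in ranked.columns:
        raise KeyError(f"ranked table lacks a {direction_col!r} column")
    sub = ranked[ranked[direction_col].astype(str).str.lower() == direction.lower()]
    genes = [_norm_gene(g) for g in sub[gene_col].tolist()[: max(n, 0)]]
    if len(genes) < n:
        logger.warning(
            "requested top %d %s regulators but table has only %d", n, direction, len(genes)
        )
    return genes


def enrichment_frequency(
    study_tables: Mapping[str, pd.DataFrame],
    pathway_col: str = "pathway",
    p_col: str = "adj_p",
) -> pd.DataFrame:
    """Rank pathways by the number of studies reporting them enriched.

    Each study table lists already-thresholded (pathway, adjusted p)
    pairs. Ties in study count break by the best (smallest) adjusted p
    across studies, then lexicographically. A single-study category is
    passed through with ``single_study=True`` so callers can fall back to
    p-value/mechanism selection.
    """
    records: dict[str, dict] = {}
    for study, table in study_tables.items():
        if len(table) == 0:
            continue
        seen = set()
        for rec in table.itertuples(index=False):
            pw = str(getattr(rec, pathway_col))
            p = float(getattr(rec, p_col))
            entry = records.setdefault(pw, {"n_studies": 0, "best_p": float("inf")})
            if pw not in seen:
                entry["n_studies"] += 1
                seen.add(pw)
            entry["best_p"] = min(entry["best_p"], p)
    single = len(study_tables) == 1
    out = pd.DataFrame(
        [
            {"pathway": pw, "n_studies": v["n_studies"], "best_p": v["best_p"]}
            for pw, v in records.items()
        ]
    )
    if len(out) == 0:
        return pd.DataFrame(columns=["pathway", "n_studies", "best_p", "single_study"])
    out = out.sort_values(
        ["n_studies", "best_p", "pathway"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out["single_study"] = single
    return out
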