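"""Proteome-transcriptome merging, concordance and target prioritization.

The merge joins significant proteins to significant transcripts on gene
symbol, labels every pair by direction agreement (concordant up,
concordant down, or contra-regulated), applies the dual-stringency
filter that defines the prioritized targets (protein q and z-score cuts
combined with transcript FDR and linear fold-change cuts), and counts
direction-matched overlaps against external study tables that may report
fold changes in any of three conventions (linear ratio, signed fold,
log2).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CONVENTIONS",
    "MISSING_TOKENS",
    "merge_omics",
    "prioritize",
    "normalize_fold",
    "cross_study_overlap",
    "overlap_percentage",
]

CONVENTIONS = ("linear_ratio", "signed_fold", "log2")

#: tokens accepted as "value not reported" in external study tables
MISSING_TOKENS = {"—", "-", "", "NA", "na", "NaN", "nan", None}

CONCORDANT_UP = "concordant_up"
CONCORDANT_DOWN = "concordant_down"
CONTRA = "contra"


def merge_omics(
    annotated: pd.DataFrame,
    transcripts: pd.DataFrame,
    sig_protein: set[str],
    sig_transcript_fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join significant proteins to significant transcripts on symbol.

    ``annotated`` is a per-protein stats frame carrying a ``symbol``
    column (see :func:`rvomics.idmap.resolve_ids`); ``sig_protein`` is
    the set of significant accessions.  Transcripts with
    fdr < ``sig_transcript_fdr`` are eligible.  Each matched pair is
    classified by the sign pair (protein log2_ratio, transcript log2fc);
    a zero effect on either side cannot be classified and is excluded
    with a warning.  Symbol collisions (e.g. multi-mapping proteins)
    are resolved by keeping the smallest protein q, ties broken on
    accession.

    Returns the pair table and a Venn summary
    {protein_only, transcript_only, shared} of significant symbols.
    """
    if (transcripts["fdr"] < transcripts["pvalue"]).any():
        log.warning("transcript table has fdr < pvalue rows; proceeding as given")
    prot = annotated[annotated["accession"].isin(sig_protein)].copy()
    prot = prot[prot["symbol"].notna()]
    tx = transcripts[transcripts["fdr"] < sig_transcript_fdr].copy()

    prot_symbols = set(prot["symbol"])
    tx_symbols = set(tx["symbol"])
    shared = prot_symbols & tx_symbols
    venn = {
        "protein_only": len(prot_symbols - tx_symbols),
        "transcript_only": len(tx_symbols - prot_symbols),
        "shared": len(shared),
    }

    n_dup = int(prot["symbol"].duplicated().sum())
    if n_dup:
        log.info("deduplicating %d protein symbol collisions by smallest q", n_dup)
    prot = prot.sort_values(["q", "accession"], kind="stable").drop_duplicates("symbol")
    tx = tx.sort_values(["fdr", "gene_id"], kind="stable").drop_duplicates("symbol")

    pairs = prot.merge(
        tx[["symbol", "log2fc", "pvalue", "fdr"]].rename(
            columns={"log2fc": "transcript_log2fc", "pvalue": "transcript_p",
                     "fdr": "transcript_fdr"}
        ),
        on="symbol", how="inner",
    )

    p_sign = np.sign(pairs["log2_ratio"].to_numpy())
    t_sign = np.sign(pairs["transcript_log2fc"].to_numpy())
    unclassifiable = (p_sign == 0) | (t_sign == 0)
    if unclassifiable.any():
        log.warning("excluding %d pairs with a zero effect on one side",
                    int(unclassifiable.sum()))
        pairs = pairs[~unclassifiable]
        p_sign, t_sign = p_sign[~unclassifiable], t_sign[~unclassifiable]
    concordance = np.where(
        p_sign != t_sign, CONTRA, np.where(p_sign > 0, CONCORDANT_UP, CONCORDANT_DOWN)
    )
    pairs = pairs.copy()
    pairs["concordance"] = concordance
    return pairs.reset_index(drop=True), venn


def prioritize(
    pairs: pd.DataFrame,
    q_max: float = 0.05,
    z_abs: float = 1.96,
    t_fdr: float = 0.05,
    t_fc: float = 1.5,
) -> pd.DataFrame:
    """Dual-stringency target filter.

    Retains pairs with protein q < ``q_max`` AND |protein z| >=
    ``z_abs`` AND transcript fdr < ``t_fdr`` AND |transcript linear
    fold| > ``t_fc`` (that is, |log2fc| > log2(t_fc)).  Sorted by
    descending |z|.
    """
    log.info("prioritize: q<%g |z|>=%g transcript fdr<%g |fold|>%g",
             q_max, z_abs, t_fdr, t_fc)
    keep = (
        (pairs["q"] < q_max)
        & (pairs["z"].abs() >= z_abs)
        & (pairs["transcript_fdr"] < t_fdr)
        & (pairs["transcript_log2fc"].abs() > math.log2(t_fc))
    )
    out = pairs[keep].copy()
    out = out.reindex(out["z"].abs().sort_values(ascending=False, kind="stable").index)
    return out.reset_index(drop=True)


def normalize_fold(value: float, convention: str) -> float:
    """Convert a reported fold change to the log2 scale.

    linear_ratio: ratios, 0.37 means down-regulation -> log2(v).
    signed_fold: magnitudes with sign, -1.66 means 1.66-fold down
    -> sign(v) * log2(|v|); values strictly inside (-1, 1) violate the
    convention and are rejected.
    log2: returned unchanged (so the conversion is idempotent).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown fold-change convention {convention!r}")
    v = float(value)
    if convention == "log2":
        return v
    if convention == "linear_ratio":
        if v <= 0:
            raise ValueError(f"linear ratio must be positive, got {v}")
        return math.log2(v)
    # signed_fold
    if -1.0 < v < 1.0:
        raise ValueError(f"signed fold magnitude below 1 is ill-defined: {v}")
    return math.copysign(math.log2(abs(v)), v)


def _parse_fold(value) -> float | None:
    """Parse an external-table fold entry; None for missing tokens."""
    if value in MISSING_TOKENS:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in MISSING_TOKENS:
            return None
        # tolerate unicode minus
        value = value.replace("−", "-")
    return float(value)


def cross_study_overlap(
    targets: pd.DataFrame, external: pd.DataFrame, convention: str | None = None
) -> tuple[int, float, pd.DataFrame]:
    """Count prioritized targets commonly regulated in an external study.

    ``external`` has columns (symbol, fold) and a declared fold-change
    convention, either as a ``convention`` column or via the argument.
    A target counts as commonly regulated iff its symbol has a reported
    (non-missing) fold in the external table AND the normalized sign
    matches the target's own direction (sign of its protein log2 ratio).
    Missing entries are absences, not zeros.

    Returns (n_common, direction-agreement fraction among reported
    entries, per-target report).
    """
    if convention is None:
        if "convention" not in external.columns:
            raise ValueError("external table must declare its fold-change convention")
        conventions = set(external["convention"])
        if len(conventions) != 1:
            raise ValueError(f"ambiguous conventions in external table: {conventions}")
        convention = conventions.pop()
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown fold-change convention {convention!r}")

    folds: dict[str, float | None] = {}
    for _, row in external.iterrows():
        folds[row["symbol"]] = _parse_fold(row["fold"])

    records = []
    for _, row in targets.iterrows():
        symbol = row["symbol"]
        target_sign = math.copysign(1.0, row["log2_ratio"])
        raw = folds.get(symbol)
        present = raw is not None
        ext_log2 = normalize_fold(raw, convention) if present else math.nan
        agrees = present and ext_log2 != 0 and math.copysign(1.0, ext_log2) == target_sign
        records.append(
            {"symbol": symbol, "reported": present, "external_log2fc": ext_log2,
             "direction_match": bool(agrees)}
        )
    report = pd.DataFrame(records)
    n_reported = int(report["reported"].sum())
    n_common = int(report["direction_match"].sum())
    agreement = n_common / n_reported if n_reported else float("nan")
    return n_common, agreement, report


def overlap_percentage(list_a: set, list_b: set) -> float:
    """Percentage of A found in B: 100 * |A ∩ B| / |A|.

    The denominator is A; report both directions when the choice
    matters.
    """
    if not list_a:
        raise ValueError("denominator set A is empty")
    log.info("overlap denominator: |A| = %d", len(list_a))
    return 100.0 * len(set(list_a) & set(list_b)) / len(set(list_a))
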