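"""File-based protein-accession to gene-identifier resolution.

Replaces a live BioMart-style lookup with a flat mapping table
(uniprot, ensembl, symbol) plus an optional curation-override table that
wins over the file mapping — mirroring the common situation where an
automated conversion leaves accessions unresolved and they are patched
by hand.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["validate_mapping", "resolve_ids"]

_REQUIRED = ("uniprot", "ensembl", "symbol")


def validate_mapping(mapping: pd.DataFrame, name: str = "mapping") -> pd.DataFrame:
    """Check required columns and reject rows with empty uniprot keys.

    Raises ValueError naming the 1-based offending row.
    """
    missing = [c for c in _REQUIRED if c not in mapping.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns: {missing}")
    keys = mapping["uniprot"]
    bad = keys.isna() | (keys.astype(str).str.strip() == "")
    if bad.any():
        row = int(bad.to_numpy().argmax()) + 1
        raise ValueError(f"{name} table row {row}: empty uniprot key")
    return mapping


def resolve_ids(
    stats: pd.DataFrame,
    mapping: pd.DataFrame,
    overrides: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Attach (ensembl, symbol) annotation to per-protein statistics.

    Overrides are applied last: any accession present in ``overrides``
    uses the curated entry (source='curated') regardless of the file
    mapping.  A protein mapping to multiple genes is expanded to one
    output row per gene and flagged ``multi_map``.  Unmapped accessions
    are kept in the output (with missing annotation) and returned as a
    list, never silently dropped.

    Resolution is idempotent: feeding an annotated table back in yields
    the same annotation.
    """
    validate_mapping(mapping)
    mapping = mapping.copy()
    if "source" not in mapping.columns:
        mapping["source"] = "file"
    if overrides is not None and len(overrides):
        validate_mapping(overrides, name="overrides")
        overrides = overrides.copy()
        overrides["source"] = "curated"
        curated_keys = set(overrides["uniprot"])
        n_shadowed = int(mapping["uniprot"].isin(curated_keys).sum())
        if n_shadowed:
            log.info("curation overrides shadow %d file mapping rows", n_shadowed)
        mapping = pd.concat(
            [mapping[~mapping["uniprot"].isin(curated_keys)],
             overrides[list(_REQUIRED) + ["source"]]],
            ignore_index=True,
        )

    # idempotence: strip any previous annotation before re-resolving
    base = stats.drop(columns=["ensembl", "symbol", "source", "multi_map"],
                      errors="ignore")
    merged = base.merge(
        mapping[["uniprot", "ensembl", "symbol", "source"]],
        left_on="accession", right_on="uniprot", how="left",
    ).drop(columns=["uniprot"])
    dup = merged["accession"].duplicated(keep=False) & merged["symbol"].notna()
    merged["multi_map"] = dup
    unmapped = list(base.loc[~base["accession"].isin(mapping["uniprot"]), "accession"])
    if unmapped:
        log.info("%d accessions left unmapped", len(unmapped))
    return merged, unmapped
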