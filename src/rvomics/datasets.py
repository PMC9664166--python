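"""Bundled reference data.

One curated table ships with the package: the 15 prioritized
protein:transcript pairs from the monocrotaline rat right-ventricle
model together with the fold changes reported for the same gene symbols
by independent pulmonary-arterial-hypertension studies (two rat strains,
two disease models, two fold-change conventions).  It serves as a small
real-world input for the prioritization and cross-study overlap
operations and as the worked example in the documentation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_targets", "reference_external_tables", "EXTERNAL_CONVENTIONS"]

#: external fold-change columns of the reference table and their conventions
EXTERNAL_CONVENTIONS = {
    "fischer_suhx_fc": "linear_ratio",
    "sd_suhx_fc": "linear_ratio",
    "mct_sd_fc": "signed_fold",
    "suhx_sd_fc": "signed_fold",
}


def load_reference_targets() -> pd.DataFrame:
    """Load the curated prioritized-pair reference table.

    Numeric protein/transcript columns are parsed to floats; the four
    external fold columns are kept as printed (dash dialects mark
    missing entries).  For filtering convenience the transcript
    significance column is exposed both as ``transcript_p`` (as printed)
    and ``transcript_fdr`` (the scale on which the published selection
    criterion is stated), and the protein log2 ratio as ``log2_ratio``
    / ``z`` / ``q`` aliases matching the pipeline's column contract.
    """
    ref = resources.files("rvomics.data") / "prioritized_pairs_reference.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("protein_z", "protein_log2fc", "protein_q",
                "transcript_log2fc", "transcript_p"):
        df[col] = df[col].astype(float)
    df["z"] = df["protein_z"]
    df["log2_ratio"] = df["protein_log2fc"]
    df["q"] = df["protein_q"]
    df["transcript_fdr"] = df["transcript_p"]
    return df


def reference_external_tables() -> dict[str, pd.DataFrame]:
    """External study tables derived from the reference table.

    Returns one (symbol, fold, convention) frame per study column,
    keeping missing-value tokens so that absence is distinguishable
    from zero.
    """
    df = load_reference_targets()
    out: dict[str, pd.DataFrame] = {}
    for col, convention in EXTERNAL_CONVENTIONS.items():
        out[col.removesuffix("_fc")] = pd.DataFrame(
            {"symbol": df["symbol"], "fold": df[col], "convention": convention}
        )
    return out
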