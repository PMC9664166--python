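"""Per-protein differential statistics for two-group label-free proteomics.

The analysis chain mirrors standard practice for LFQ intensity matrices:

1. zeros (non-detections) are replaced by a low quantile of each sample's
   observed (nonzero) intensities;
2. proteins must have a minimum number of originally-positive values in
   each group to progress (presence filter);
3. group means, MCT/control ratio and log2 ratio are computed on the
   linear scale;
4. log2 ratios are standardized across proteins into z-scores;
5. p-values come from an empirical-Bayes moderated t-statistic in which
   per-protein variances are shrunk toward a prior estimated by the
   method of moments on the log residual variances;
6. Benjamini-Hochberg step-up q-values control the false discovery rate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import IntensityMatrix

log = logging.getLogger(__name__)

__all__ = [
    "impute_zeros",
    "presence_filter",
    "positive_counts",
    "effect_stats",
    "add_zscores",
    "squeeze_variances",
    "moderated_test",
    "bh_adjust",
    "classify_significant",
    "run_differential",
]


def impute_zeros(m: IntensityMatrix, quantile: float = 0.01) -> IntensityMatrix:
    """Replace zero intensities with a per-sample low-abundance floor.

    Each zero cell becomes the ``quantile`` quantile (default: the 1st
    percentile) of the *nonzero* intensities of its own sample column,
    computed by sorting and linear interpolation.  Nonzero cells are
    never altered.

    Raises
    ------
    ValueError
        If a sample column contains no nonzero value (the replacement
        would be undefined); the error names the sample.
    """
    if not 0 <= quantile <= 1:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    out = m.intensities.copy()
    for col in out.columns:
        values = out[col].to_numpy(dtype=float)
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {col!r} is entirely zero; imputation undefined")
        if (values == 0).any():
            floor = float(np.quantile(nonzero, quantile))
            values[values == 0] = floor
            out[col] = values
    return IntensityMatrix(out, m.design, m.control, m.case)


def positive_counts(m: IntensityMatrix) -> pd.DataFrame:
    """Count originally-positive (nonzero) values per protein per group."""
    pos = m.intensities > 0
    return pd.DataFrame(
        {
            "n_pos_control": pos[m.control_columns].sum(axis=1),
            "n_pos_mct": pos[m.case_columns].sum(axis=1),
        }
    )


def presence_filter(
    m: IntensityMatrix, min_pos: int = 3
) -> tuple[IntensityMatrix, list[str]]:
    """Retain proteins with >= ``min_pos`` positive values in each group.

    Positivity is judged on the matrix as given, so apply this to the
    original (pre-imputation) matrix.  Returns the filtered matrix and
    the list of dropped accessions.
    """
    n_ctrl = len(m.control_columns)
    n_case = len(m.case_columns)
    if min_pos > min(n_ctrl, n_case):
        raise ValueError(
            f"min_pos={min_pos} exceeds the smaller group size {min(n_ctrl, n_case)}"
        )
    counts = positive_counts(m)
    keep = (counts["n_pos_control"] >= min_pos) & (counts["n_pos_mct"] >= min_pos)
    dropped = list(m.accessions[~keep])
    if dropped:
        log.info("presence filter (min_pos=%d) dropped %d proteins", min_pos, len(dropped))
    return m.subset(m.accessions[keep]), dropped


def effect_stats(m: IntensityMatrix) -> pd.DataFrame:
    """Group means (linear scale), MCT/control ratio and log2 ratio."""
    mean_control = m.intensities[m.control_columns].mean(axis=1)
    mean_mct = m.intensities[m.case_columns].mean(axis=1)
    if (mean_control <= 0).any():
        raise ValueError("non-positive control mean; was the matrix imputed?")
    ratio = mean_mct / mean_control
    stats_df = pd.DataFrame(
        {
            "accession": m.accessions,
            "mean_control": mean_control.to_numpy(),
            "mean_mct": mean_mct.to_numpy(),
            "ratio": ratio.to_numpy(),
            "log2_ratio": np.log2(ratio.to_numpy()),
        }
    )
    return stats_df


def add_zscores(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Standardize log2 ratios across proteins: z = (x - mean) / SD(n-1).

    The resulting z vector has mean 0 and sample standard deviation 1.
    """
    if len(stats_df) < 2:
        raise ValueError("z-scores need at least two proteins")
    x = stats_df["log2_ratio"].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread of log2 ratios; z-scores undefined")
    out = stats_df.copy()
    out["z"] = (x - x.mean()) / sd
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, df_resid: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-protein variances.

    Models the per-protein residual variances ``s2`` (each with
    ``df_resid`` degrees of freedom) as scaled-F distributed around a
    prior variance s0^2 with prior degrees of freedom d0, and estimates
    (d0, s0^2) by the method of moments on log s2: with
    e_g = log s2_g - digamma(d_g/2) + log(d_g/2), the excess variance of
    e over trigamma(d_g/2) identifies trigamma(d0/2).

    Returns (df_prior, s2_prior, s2_posterior) with
    s2_posterior = (d0*s0^2 + d_g*s2) / (d0 + d_g).
    ``df_prior`` is ``inf`` when the observed variances are no more
    dispersed than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 < 0).any():
        raise ValueError("variances must be non-negative")
    if df_resid <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    # guard exact zeros before taking logs
    floor = max(s2[s2 > 0].min() * 1e-12, 1e-300) if (s2 > 0).any() else 1e-300
    z = np.log(np.maximum(s2, floor))
    half = df_resid / 2.0
    e = z - special.digamma(half) + np.log(half)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, half)
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s2_prior = float(
            np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s2_prior)
    return df_prior, s2_prior, s2_post


def moderated_test(m: IntensityMatrix, ordinary: bool = False) -> pd.DataFrame:
    """Two-group moderated t-test on log2 intensities.

    Fits the per-protein two-sample comparison on log2(intensity), pools
    the within-group variance (d_g = n1 + n2 - 2 df), shrinks it toward
    the moment-estimated prior, and evaluates the t statistic against a
    t distribution with d0 + d_g degrees of freedom.  With
    ``ordinary=True`` no shrinkage is applied (classic pooled t), which
    is also the d0 -> 0 limit of the moderated statistic.

    Returns a frame with accession, t, df_total, s2, s2_post and p.
    """
    ctrl = m.intensities[m.control_columns].to_numpy(dtype=float)
    case = m.intensities[m.case_columns].to_numpy(dtype=float)
    n1, n2 = ctrl.shape[1], case.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("need at least two samples per group")
    if (ctrl <= 0).any() or (case <= 0).any():
        raise ValueError("log2 model needs strictly positive intensities; impute first")
    lc = np.log2(ctrl)
    lm = np.log2(case)
    diff = lm.mean(axis=1) - lc.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = lc.var(axis=1, ddof=1) * (n1 - 1) + lm.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    if ordinary:
        df_prior, s2_post = 0.0, s2
    else:
        df_prior, _, s2_post = squeeze_variances(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    df_total = df_resid + df_prior
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "accession": m.accessions,
            "t": t,
            "df_total": df_total,
            "s2": s2,
            "s2_post": s2_post,
            "p": p,
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.  Ties are handled by a stable sort so the output is
    deterministic.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m_tests = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m_tests / np.arange(1, m_tests + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m_tests)
    q[order] = q_sorted
    return q


def classify_significant(
    stats_df: pd.DataFrame, q_max: float = 0.05, z_abs: float = 1.96
) -> tuple[set[str], set[str]]:
    """Split proteins into the significant and stringent sets.

    significant: q < q_max (strict).  stringent: additionally
    |z| >= z_abs (inclusive, so a protein printed at the cut-off is
    retained).  The stringent set is a subset of the significant set.
    """
    sig_mask = stats_df["q"] < q_max
    strict_mask = sig_mask & (stats_df["z"].abs() >= z_abs)
    significant = set(stats_df.loc[sig_mask, "accession"])
    stringent = set(stats_df.loc[strict_mask, "accession"])
    return significant, stringent


def run_differential(
    raw: IntensityMatrix,
    quantile: float = 0.01,
    min_pos: int = 3,
    ordinary: bool = False,
    median_normalize: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Full per-protein differential chain on a raw intensity matrix.

    Imputes zeros with the per-sample low quantile computed on the full
    matrix, presence-filters on the original (pre-imputation) zero
    pattern, and computes means, ratios, z-scores, (moderated) p-values
    and BH q-values on the retained proteins.  ``median_normalize``
    rescales each sample to the global median of sample medians before
    testing (off by default).  Returns (per-protein stats frame, dropped
    accessions).
    """
    log.info(
        "differential analysis: quantile=%g min_pos=%d ordinary=%s median_normalize=%s",
        quantile, min_pos, ordinary, median_normalize,
    )
    imputed_full = impute_zeros(raw, quantile=quantile)
    kept, dropped = presence_filter(raw, min_pos=min_pos)
    counts = positive_counts(kept)
    imputed = imputed_full.subset(kept.accessions)
    if median_normalize:
        data = imputed.intensities
        medians = data.median(axis=0)
        target = float(medians.median())
        imputed = IntensityMatrix(
            data * (target / medians), imputed.design, imputed.control, imputed.case
        )
    stats_df = add_zscores(effect_stats(imputed))
    tested = moderated_test(imputed, ordinary=ordinary)
    stats_df = stats_df.merge(tested[["accession", "t", "df_total", "p"]], on="accession")
    stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())
    stats_df["n_pos_control"] = counts["n_pos_control"].to_numpy()
    stats_df["n_pos_mct"] = counts["n_pos_mct"].to_numpy()
    return stats_df, dropped
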