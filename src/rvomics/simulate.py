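"""Synthetic multi-omic inputs with known ground truth.

Emulates the statistical structure of the study design the pipeline
targets: a ~3,100-protein x 10-sample (5 control vs 5 MCT) label-free
intensity matrix with intensity-dependent zero dropouts and planted
group effects, a transcript differential-expression table whose planted
effects are concordant with the protein effects at a controlled rate, a
protein-to-gene mapping table with a controlled unmapped fraction, and a
gene-to-GO annotation table with one term deliberately enriched among
the planted differential genes.

Randomness is driven by `numpy.random.default_rng` seeded from
``SimConfig.seed`` with one documented child stream per generator
(stream 0: proteome, 1: transcriptome, 2: mapping/annotation).  Within a
stream, draws occur in a fixed documented order so that counts (e.g. the
number of planted contra-regulated pairs) can be replayed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import IntensityMatrix, write_tsv
from .proteomics import bh_adjust

__all__ = ["SimConfig", "GroundTruth", "gen_proteome", "gen_transcriptome",
           "gen_mapping_and_go", "gen_external_study", "write_simulation"]

_PROTEOME_STREAM = 0
_TRANSCRIPTOME_STREAM = 1
_MAPPING_STREAM = 2
_EXTERNAL_STREAM = 3

#: fraction of additional transcript-only genes relative to n_proteins
_TRANSCRIPT_ONLY_FRAC = 0.3
#: SD of null (non-differential) transcript log2 fold changes
_NULL_TRANSCRIPT_SD = 0.15
#: within-group log2 SD is reused as the protein->transcript effect jitter


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the target study's scale: ~3,100 detected proteins,
    5 animals per group, ~10% of proteins with a planted group effect of
    2 on the log2 scale against a within-group SD of 0.5.
    """

    n_proteins: int = 3100
    n_per_group: int = 5
    frac_de: float = 0.10
    effect_log2: float = 2.0
    sigma_within: float = 0.5
    baseline_log2_mean: float = 23.0
    baseline_log2_sd: float = 2.0
    dropout_intercept: float = 8.0
    dropout_slope: float = -0.5
    concordance_rate: float = 0.9
    frac_mapped: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "concordance_rate", "frac_mapped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.sigma_within <= 0:
            raise ValueError("sigma_within must be positive")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if self.n_proteins < 2:
            raise ValueError("need at least two proteins")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted truth for a simulation run.

    ``proteins`` always holds accession, gene_id, symbol, is_de and
    true_log2fc (exactly 0 where is_de is False).  ``transcripts`` and
    ``mapping`` are filled in by :func:`gen_transcriptome` and
    :func:`gen_mapping_and_go`.
    """

    proteins: pd.DataFrame
    transcripts: pd.DataFrame | None = None
    mapping: pd.DataFrame | None = None

    @property
    def n_de(self) -> int:
        return int(self.proteins["is_de"].sum())


def _accession(i: int) -> str:
    return f"P{i:05d}"


def _gene_id(i: int) -> str:
    return f"ENSRNOG{i:08d}"


def _symbol(i: int) -> str:
    return f"Gene{i:04d}"


def gen_proteome(cfg: SimConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate the label-free intensity matrix with planted effects.

    Latent log2 intensities are Gaussian: a per-protein baseline plus
    within-group noise, with the planted effect added to the MCT columns
    of differential proteins (direction 50/50 up/down, magnitude
    ``effect_log2``).  Cells drop out to literal zero with probability
    expit(intercept + slope * latent_log2), so low-abundance cells are
    missing more often.  Draw order within stream 0: DE rows, directions,
    baselines, noise matrix, dropout uniforms.
    """
    rng = cfg.rng(_PROTEOME_STREAM)
    n, k = cfg.n_proteins, cfg.n_per_group
    n_de = round(cfg.frac_de * n)

    de_rows = np.sort(rng.choice(n, size=n_de, replace=False))
    direction = rng.choice([-1.0, 1.0], size=n_de)
    true_log2fc = np.zeros(n)
    true_log2fc[de_rows] = direction * cfg.effect_log2
    is_de = np.zeros(n, dtype=bool)
    is_de[de_rows] = True

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    noise = rng.normal(0.0, cfg.sigma_within, size=(n, 2 * k))
    latent = baseline[:, None] + noise
    latent[:, k:] += true_log2fc[:, None]

    p_drop = expit(cfg.dropout_intercept + cfg.dropout_slope * latent)
    dropped = rng.random(size=latent.shape) < p_drop

    intensities = np.power(2.0, latent)
    intensities[dropped] = 0.0

    samples = [f"control_{j + 1}" for j in range(k)] + [f"MCT_{j + 1}" for j in range(k)]
    accessions = [_accession(i) for i in range(n)]
    matrix = IntensityMatrix(
        pd.DataFrame(intensities, index=pd.Index(accessions, name="accession"),
                     columns=samples),
        pd.Series(["control"] * k + ["MCT"] * k, index=samples),
    )
    truth = GroundTruth(
        proteins=pd.DataFrame(
            {
                "accession": accessions,
                "gene_id": [_gene_id(i) for i in range(n)],
                "symbol": [_symbol(i) for i in range(n)],
                "is_de": is_de,
                "true_log2fc": true_log2fc,
            }
        )
    )
    return matrix, truth


def gen_transcriptome(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate the transcript differential-expression table.

    For every protein-coding gene in ``truth`` a transcript row is
    produced.  Transcripts of differential proteins are planted with the
    protein's direction with probability ``concordance_rate`` and the
    opposite direction otherwise; magnitudes are jittered around
    ``effect_log2``.  Non-differential genes get null effects.  A block
    of transcript-only genes (30% of n_proteins, ids disjoint from the
    proteome) makes the downstream merge a proper partial join.

    Draw order within stream 1: concordance uniforms for DE proteins in
    row order, DE magnitudes, DE -log10 p exponents, null log2 FCs, null
    p-values, then the same three kinds of draws for the extra genes.
    Records the planted transcript truth on ``truth.transcripts``.
    """
    rng = cfg.rng(_TRANSCRIPTOME_STREAM)
    prot = truth.proteins
    de_mask = prot["is_de"].to_numpy()
    n = len(prot)
    n_de = int(de_mask.sum())

    concordant_u = rng.random(n_de)
    concordant = concordant_u < cfg.concordance_rate
    magnitudes = np.abs(rng.normal(cfg.effect_log2, cfg.sigma_within, size=n_de))
    de_exponents = rng.uniform(4.0, 20.0, size=n_de)
    null_lfc = rng.normal(0.0, _NULL_TRANSCRIPT_SD, size=n - n_de)
    null_p = rng.uniform(0.0, 1.0, size=n - n_de)

    protein_sign = np.sign(prot.loc[de_mask, "true_log2fc"].to_numpy())
    t_sign = np.where(concordant, protein_sign, -protein_sign)

    log2fc = np.empty(n)
    pvals = np.empty(n)
    log2fc[de_mask] = t_sign * magnitudes
    pvals[de_mask] = np.power(10.0, -de_exponents)
    log2fc[~de_mask] = null_lfc
    pvals[~de_mask] = null_p

    n_extra = round(_TRANSCRIPT_ONLY_FRAC * cfg.n_proteins)
    n_extra_de = round(cfg.frac_de * n_extra)
    extra_sign = rng.choice([-1.0, 1.0], size=n_extra_de)
    extra_mag = np.abs(rng.normal(cfg.effect_log2, cfg.sigma_within, size=n_extra_de))
    extra_exp = rng.uniform(4.0, 20.0, size=n_extra_de)
    extra_lfc = np.concatenate(
        [extra_sign * extra_mag, rng.normal(0.0, _NULL_TRANSCRIPT_SD, size=n_extra - n_extra_de)]
    )
    extra_p = np.concatenate(
        [np.power(10.0, -extra_exp), rng.uniform(0.0, 1.0, size=n_extra - n_extra_de)]
    )

    offset = 90_000_000  # transcript-only id block, disjoint from proteome genes
    gene_ids = list(prot["gene_id"]) + [_gene_id(offset + i) for i in range(n_extra)]
    symbols = list(prot["symbol"]) + [f"TGene{i:04d}" for i in range(n_extra)]
    all_lfc = np.concatenate([log2fc, extra_lfc])
    all_p = np.concatenate([pvals, extra_p])
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "log2fc": all_lfc,
            "pvalue": all_p,
            "fdr": bh_adjust(all_p),
        }
    )

    t_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "is_de": np.concatenate(
                [de_mask, np.arange(n_extra) < n_extra_de]
            ),
            "true_log2fc": np.concatenate(
                [np.where(de_mask, log2fc, 0.0), np.where(np.arange(n_extra) < n_extra_de, extra_lfc, 0.0)]
            ),
        }
    )
    concordant_full = np.full(n, False)
    concordant_full[np.flatnonzero(de_mask)] = concordant
    t_truth["concordant_with_protein"] = np.concatenate(
        [concordant_full, np.full(n_extra, False)]
    )
    truth.transcripts = t_truth
    return table


def gen_mapping_and_go(
    cfg: SimConfig, truth: GroundTruth, n_terms: tuple[int, int, int] = (30, 15, 15),
    max_terms_per_gene: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the protein-to-gene mapping and GO annotation tables.

    The mapping covers exactly round(frac_mapped * n_proteins) protein
    accessions (chosen at random; the rest stay unmapped so curation
    overrides are exercised).  Annotation assigns each proteome gene 0 to
    ``max_terms_per_gene`` terms per domain draw across BP/CC/MF, and one
    designated BP term (``GO:9000001``, "planted differential process")
    is assigned to planted-DE genes with high probability so that
    over-representation is guaranteed detectable.

    Draw order within stream 2: mapped-row choice, per-domain term
    assignment matrices, enriched-term uniforms.  Records coverage on
    ``truth.mapping``.
    """
    rng = cfg.rng(_MAPPING_STREAM)
    prot = truth.proteins
    n = len(prot)
    n_mapped = round(cfg.frac_mapped * n)
    mapped_rows = np.sort(rng.choice(n, size=n_mapped, replace=False))
    mapping = prot.iloc[mapped_rows][["accession", "gene_id", "symbol"]].rename(
        columns={"accession": "uniprot", "gene_id": "ensembl"}
    )
    mapping = mapping.reset_index(drop=True)
    mapping["source"] = "file"

    domains = [("BP", n_terms[0]), ("CC", n_terms[1]), ("MF", n_terms[2])]
    rows: list[tuple[str, str, str, str]] = []
    term_index = 0
    for domain, k_terms in domains:
        # each gene draws 0..max_terms_per_gene terms from this domain
        counts = rng.integers(0, max_terms_per_gene + 1, size=n)
        for g in range(n):
            if counts[g] == 0:
                continue
            terms = rng.choice(k_terms, size=counts[g], replace=False)
            for t in terms:
                rows.append(
                    (
                        prot["symbol"].iat[g],
                        f"GO:{term_index + t + 1:07d}",
                        domain,
                        f"{domain.lower()} term {t + 1}",
                    )
                )
        term_index += k_terms

    enriched_term = "GO:9000001"
    is_de = prot["is_de"].to_numpy()
    u = rng.random(n)
    assign = np.where(is_de, u < 0.6, u < 0.05)
    for g in np.flatnonzero(assign):
        rows.append((prot["symbol"].iat[g], enriched_term, "BP", "planted differential process"))

    ann = pd.DataFrame(rows, columns=["symbol", "go_id", "domain", "term_name"])
    ann = ann.drop_duplicates(subset=["symbol", "go_id"]).reset_index(drop=True)

    truth.mapping = pd.DataFrame(
        {
            "accession": prot["accession"],
            "is_mapped": np.isin(np.arange(n), mapped_rows),
        }
    )
    return mapping, ann


def gen_external_study(
    cfg: SimConfig,
    truth: GroundTruth,
    convention: str = "signed_fold",
    missing_rate: float = 0.3,
    flip_rate: float = 0.05,
    label: int = 0,
) -> pd.DataFrame:
    """Simulate an external study's fold-change table in a chosen convention.

    Takes the planted transcript truth, reports each differential gene
    with probability 1 - ``missing_rate`` (missing entries become the
    em-dash token, as published tables print them), flips the direction
    with probability ``flip_rate``, and encodes the fold in the
    requested convention (``linear_ratio``, ``signed_fold`` or
    ``log2``).  ``label`` separates the RNG substream so several
    distinct studies can be drawn from one config.
    """
    if truth.transcripts is None:
        raise ValueError("generate the transcriptome before external studies")
    rng = np.random.default_rng([cfg.seed, _EXTERNAL_STREAM, label])
    de = truth.transcripts[truth.transcripts["is_de"]].reset_index(drop=True)
    n = len(de)
    reported = rng.random(n) >= missing_rate
    flipped = rng.random(n) < flip_rate
    jitter = rng.normal(1.0, 0.2, size=n).clip(0.5, 2.0)

    folds: list[str] = []
    for i in range(n):
        if not reported[i]:
            folds.append("—")
            continue
        log2fc = de["true_log2fc"].iat[i] * jitter[i]
        if flipped[i]:
            log2fc = -log2fc
        if convention == "log2":
            folds.append(f"{log2fc:.4g}")
        elif convention == "linear_ratio":
            folds.append(f"{2.0 ** log2fc:.4g}")
        elif convention == "signed_fold":
            mag = 2.0 ** abs(log2fc)
            folds.append(f"{math.copysign(mag, log2fc):.4g}")
        else:
            raise ValueError(f"unknown fold-change convention {convention!r}")
    return pd.DataFrame(
        {"symbol": de["symbol"], "fold": folds, "convention": convention}
    )


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate all synthetic inputs and write them as TSVs.

    Produces intensity matrix, design, transcript table, mapping,
    annotation and ground-truth tables; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = gen_proteome(cfg)
    transcripts = gen_transcriptome(cfg, truth)
    mapping, ann = gen_mapping_and_go(cfg, truth)
    ext_a = gen_external_study(cfg, truth, convention="linear_ratio", label=0)
    ext_b = gen_external_study(cfg, truth, convention="signed_fold", label=1)

    paths = {
        "matrix": outdir / "intensities.tsv",
        "design": outdir / "design.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "mapping": outdir / "mapping.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth_proteins": outdir / "truth_proteins.tsv",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
        "truth_mapping": outdir / "truth_mapping.tsv",
        "external_a": outdir / "external_study_a.tsv",
        "external_b": outdir / "external_study_b.tsv",
    }
    matrix.to_tsv(paths["matrix"], paths["design"])
    write_tsv(transcripts, paths["transcripts"])
    write_tsv(mapping, paths["mapping"])
    write_tsv(ann, paths["annotation"])
    write_tsv(ext_a, paths["external_a"])
    write_tsv(ext_b, paths["external_b"])
    write_tsv(truth.proteins, paths["truth_proteins"])
    write_tsv(truth.transcripts, paths["truth_transcripts"])
    write_tsv(truth.mapping, paths["truth_mapping"])
    return paths
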