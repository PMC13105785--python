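"""Synthetic cohort, microbiome and GWAS generators with planted truth.

Every input the pipeline consumes can be generated here with a recorded
ground truth, so each downstream stage (toxicity grading, diversity tests,
multivariable associations, co-occurrence networks, Mendelian
randomization) is testable against known effects without any external data.

The generators are pure functions of their parameter objects, including the
seed: a single global seed expands to per-component child seeds by fixed
offsets, so each stage is reproducible on its own.

* ``simulate_cohort`` draws a chemoradiotherapy cohort whose weekly blood
  counts decline multiplicatively from baseline with lognormal noise; the
  planted sex effect acts on the weekly decline rate (not the baseline),
  modelling a treatment-induced disparity, and an oxaliplatin effect adds
  extra lymphocyte decline for patients on the oxaliplatin-containing
  regimen.
* ``simulate_microbiome`` draws 4-time-point compositional count tables
  (Dirichlet-multinomial around a log-normal basis) with sex- and
  toxicity-associated taxa planted as log-scale shifts, plus log-normal
  metabolite intensity tables with linear log-scale effects.
* ``simulate_gwas_pair`` draws exposure/outcome GWAS summary statistics with
  a known causal effect, optional directional pleiotropy, and a
  block-diagonal AR(1) LD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortParams",
    "MicrobiomeSimParams",
    "GwasSimParams",
    "GwasPair",
    "simulate_cohort",
    "simulate_microbiome",
    "simulate_gwas_pair",
    "child_seed",
]

ANALYTES = ("wbc", "anc", "alc", "hgb", "plt")

# fixed offsets expanding the global seed into per-component streams
_SEED_OFFSETS = {"cohort": 0, "microbiome": 1, "gwas": 2, "metabolites": 3}


def child_seed(seed: int, component: str) -> int:
    """Derive a per-component child seed from the global seed."""
    return (int(seed) + _SEED_OFFSETS[component]) % (2**31)


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-generator settings.

    Baselines are population-typical adult values (10^9/L for cell counts,
    g/L for hemoglobin); weekly declines are per-analyte multiplicative
    factors chosen so that the induced AE grade mix is dominated by
    lymphopenia, as is characteristic of pelvic chemoradiotherapy.
    ``sex_effect`` multiplies the weekly decline of the affected sex
    (values < 1 mean faster decline, i.e. worse toxicity); ``oxaliplatin_effect``
    does the same for lymphocytes of patients on oxaliplatin.
    """

    n_patients: int = 329
    male_fraction: float = 238 / 329
    n_weeks: int = 5
    baseline_means: dict[str, float] = field(
        default_factory=lambda: {"wbc": 6.6, "anc": 4.2, "alc": 1.9,
                                 "hgb": 140.0, "plt": 250.0}
    )
    weekly_decline: dict[str, float] = field(
        default_factory=lambda: {"wbc": 0.91, "anc": 0.90, "alc": 0.80,
                                 "hgb": 0.98, "plt": 0.95}
    )
    sex_effect: float = 0.95  # extra weekly decline applied to females
    affected_sex: str = "female"
    oxaliplatin_fraction: float = 0.35
    oxaliplatin_effect: float = 0.93  # extra weekly decline on lymphocytes
    # lognormal scale; scalar or per-analyte (hemoglobin varies far less
    # week to week than leukocyte counts)
    noise_sd: float | dict[str, float] = field(
        default_factory=lambda: {"wbc": 0.18, "anc": 0.20, "alc": 0.20,
                                 "hgb": 0.06, "plt": 0.12}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        _check_fraction("male_fraction", self.male_fraction)
        _check_fraction("oxaliplatin_fraction", self.oxaliplatin_fraction)
        for name, d in self.weekly_decline.items():
            if not 0.0 < d <= 1.0:
                raise ValueError(f"weekly_decline[{name!r}] must be in (0, 1], got {d}")
        for name in ("sex_effect", "oxaliplatin_effect"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        noise = self.noise_sd
        if isinstance(noise, dict):
            if set(noise) != set(ANALYTES):
                raise ValueError(f"noise_sd dict must cover {ANALYTES}")
            bad = any(v < 0 for v in noise.values())
        else:
            bad = noise < 0
        if bad:
            raise ValueError("noise_sd must be >= 0")
        if set(self.baseline_means) != set(ANALYTES) or set(self.weekly_decline) != set(ANALYTES):
            raise ValueError(f"baseline_means and weekly_decline must cover {ANALYTES}")


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw patient metadata and weekly lab series.

    Returns ``(metadata, labs)``: one metadata row per patient (sex, age,
    tumor location/stage, nodal status, differentiation, oxaliplatin flag)
    and a long-format lab frame (patient_id, week, analyte, value) with
    ``n_weeks + 1`` entries per analyte, week 0 being the pre-treatment
    baseline.  All values are positive by construction (multiplicative
    lognormal noise).
    """
    rng = np.random.default_rng(child_seed(params.seed, "cohort"))
    n = params.n_patients
    pid = [f"P{i:04d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < params.male_fraction, "male", "female")
    age = np.clip(np.round(rng.normal(57, 10, n)), 18, 80).astype(int)
    location = rng.choice(["low", "mid-high"], n, p=[0.59, 0.41])
    t_stage = rng.choice(["cT2", "cT3", "cT4"], n, p=[0.10, 0.69, 0.21])
    n_stage = rng.choice(["cN-", "cN+"], n, p=[0.08, 0.92])
    differentiation = rng.choice(["well", "moderate", "poor"], n, p=[0.1, 0.7, 0.2])
    oxaliplatin = rng.random(n) < params.oxaliplatin_fraction
    metadata = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "age": age,
            "location": location,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "differentiation": differentiation,
            "oxaliplatin": oxaliplatin,
        }
    )

    noise_sd = (
        params.noise_sd
        if isinstance(params.noise_sd, dict)
        else {a: params.noise_sd for a in ANALYTES}
    )
    weeks = np.arange(params.n_weeks + 1)
    affected = sex == params.affected_sex
    frames = []
    for analyte in ANALYTES:
        sd = noise_sd[analyte]
        base = params.baseline_means[analyte] * np.exp(rng.normal(0.0, sd, n))
        decline = np.full(n, params.weekly_decline[analyte])
        decline[affected] *= params.sex_effect
        if analyte == "alc":
            decline[oxaliplatin] *= params.oxaliplatin_effect
        noise = np.exp(rng.normal(0.0, sd, (n, len(weeks))))
        noise[:, 0] = 1.0  # week 0 is the drawn baseline itself
        values = base[:, None] * decline[:, None] ** weeks[None, :] * noise
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(pid, len(weeks)),
                    "week": np.tile(weeks, n),
                    "analyte": analyte,
                    "value": values.ravel(),
                }
            )
        )
    labs = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["patient_id", "analyte", "week"], kind="stable")
        .reset_index(drop=True)
    )
    return metadata, labs


@dataclass(frozen=True)
class MicrobiomeSimParams:
    """Microbiome/metabolome generator settings.

    Taxon log-abundance baselines are drawn N(basis_mean, basis_sd); sample
    compositions are softmax of the shifted log-abundances, drawn
    Dirichlet(overdispersion x p) then multinomial at ``depth`` reads.
    ``sex_assoc_taxa`` / ``hti_assoc_taxa`` plant log-fold effects (per HTI
    unit for the latter).  ``time_dip`` widens the log-abundance spread of
    low-HTI samples from ``dip_timepoint`` on, lowering their alpha
    diversity mid-treatment with a slow recovery (the dip decays by
    ``dip_recovery`` per subsequent time point) — the qualitative
    longitudinal pattern the generator emulates; 0 disables it.
    """

    n_taxa: int = 150
    n_timepoints: int = 4
    depth: int = 50_000
    basis_mean: float = 0.0
    basis_sd: float = 2.0
    sex_assoc_taxa: Sequence[tuple[str, float]] = ()
    hti_assoc_taxa: Sequence[tuple[str, float]] = ()
    overdispersion: float = 200.0
    time_dip: float = 0.5
    dip_timepoint: int = 2
    dip_recovery: float = 0.5
    n_metabolites: int = 50
    sex_assoc_metabolites: Sequence[tuple[str, float]] = ()
    hti_assoc_metabolites: Sequence[tuple[str, float]] = ()
    metabolite_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion (concentration) must be > 0")
        if self.n_taxa < 2 or self.n_timepoints < 1:
            raise ValueError("need n_taxa >= 2 and n_timepoints >= 1")


def taxon_names(n: int) -> list[str]:
    return [f"sp_{i:03d}" for i in range(1, n + 1)]


def simulate_microbiome(
    metadata: pd.DataFrame,
    hti: pd.Series,
    params: MicrobiomeSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw longitudinal taxon counts and metabolite intensities.

    Returns ``(counts, metabolites, sample_meta, truth)``.  ``counts`` is
    samples x taxa with every row summing exactly to ``depth``;
    ``metabolites`` is samples x metabolites (log-normal intensities);
    ``sample_meta`` carries patient covariates, timepoint, HTI and HTI group
    per sample; ``truth`` records every planted effect.
    """
    taxa = taxon_names(params.n_taxa)
    mets = [f"met_{i:03d}" for i in range(1, params.n_metabolites + 1)]
    for name, _ in list(params.sex_assoc_taxa) + list(params.hti_assoc_taxa):
        if name not in taxa:
            raise ValueError(f"taxon {name!r} named in effects absent from basis")
    for name, _ in list(params.sex_assoc_metabolites) + list(params.hti_assoc_metabolites):
        if name not in mets:
            raise ValueError(f"metabolite {name!r} named in effects absent from basis")
    hti = pd.Series(hti)
    hti.index = hti.index.astype(str)
    missing = set(metadata["patient_id"].astype(str)) - set(hti.index)
    if missing:
        raise ValueError(f"missing HTI values for patients {sorted(missing)[:5]}")

    rng = np.random.default_rng(child_seed(params.seed, "microbiome"))
    mu = rng.normal(params.basis_mean, params.basis_sd, params.n_taxa)
    sex_shift = np.zeros(params.n_taxa)
    hti_shift = np.zeros(params.n_taxa)
    for name, lfc in params.sex_assoc_taxa:
        sex_shift[taxa.index(name)] = lfc
    for name, lfc in params.hti_assoc_taxa:
        hti_shift[taxa.index(name)] = lfc

    hti_median = float(hti.loc[metadata["patient_id"].astype(str)].median())
    count_rows, meta_rows = [], []
    for _, pat in metadata.iterrows():
        pid = str(pat["patient_id"])
        h = float(hti.loc[pid])
        female = pat["sex"] == "female"
        low_group = h <= hti_median
        for t in range(1, params.n_timepoints + 1):
            log_a = mu + female * sex_shift + h * hti_shift
            if params.time_dip and low_group and t >= params.dip_timepoint:
                dip = params.time_dip * params.dip_recovery ** (t - params.dip_timepoint)
                centered = log_a - log_a.mean()
                log_a = log_a.mean() + centered * (1.0 + dip)
            p = np.exp(log_a - log_a.max())
            p /= p.sum()
            alpha = params.overdispersion * p
            comp = rng.dirichlet(alpha)
            counts = rng.multinomial(params.depth, comp)
            count_rows.append(counts)
            meta_rows.append(
                dict(pat) | {"sample_id": f"{pid}_T{t}", "timepoint": t,
                             "hti": h, "hti_group": "low" if low_group else "high"}
            )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = pd.DataFrame(count_rows, index=sample_meta.index, columns=taxa)

    # metabolites: log-normal intensities with linear log-scale effects
    met_rng = np.random.default_rng(child_seed(params.seed, "metabolites"))
    nu = met_rng.normal(10.0, 1.0, params.n_metabolites)
    m_sex = np.zeros(params.n_metabolites)
    m_hti = np.zeros(params.n_metabolites)
    for name, lfc in params.sex_assoc_metabolites:
        m_sex[mets.index(name)] = lfc
    for name, lfc in params.hti_assoc_metabolites:
        m_hti[mets.index(name)] = lfc
    female_flag = (sample_meta["sex"] == "female").values[:, None]
    h_col = sample_meta["hti"].values[:, None]
    log_int = (
        nu[None, :]
        + female_flag * m_sex[None, :]
        + h_col * m_hti[None, :]
        + met_rng.normal(0.0, params.metabolite_sigma, (len(sample_meta), params.n_metabolites))
    )
    metabolites = pd.DataFrame(np.exp(log_int), index=sample_meta.index, columns=mets)

    truth = {
        "sex_assoc_taxa": list(params.sex_assoc_taxa),
        "hti_assoc_taxa": list(params.hti_assoc_taxa),
        "sex_assoc_metabolites": list(params.sex_assoc_metabolites),
        "hti_assoc_metabolites": list(params.hti_assoc_metabolites),
        "time_dip": params.time_dip,
        "dip_timepoint": params.dip_timepoint,
        "hti_median": hti_median,
    }
    return counts, metabolites, sample_meta, truth


@dataclass(frozen=True)
class GwasSimParams:
    """Exposure/outcome summary-statistic generator settings.

    Instrument SNPs (one per LD block, so they survive clumping) carry
    positive exposure effects drawn U(0.08, 0.25) with small standard
    errors, guaranteeing genome-wide-suggestive p-values; remaining SNPs are
    null.  Outcome effects are ``true_effect x beta_exposure + pleiotropy +
    noise``; pleiotropy is drawn N(pleiotropy_mean, pleiotropy_sd) per SNP.
    The LD matrix is block-diagonal AR(1) with correlation ``ld_rho``.
    """

    n_snps: int = 200
    n_instruments: int = 50
    true_effect: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_block_size: int = 4
    ld_rho: float = 0.3
    exposure_se: float = 0.01
    outcome_se: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments > self.n_snps // self.ld_block_size:
            raise ValueError(
                "n_instruments must be <= n_snps / ld_block_size "
                "(one instrument per LD block)"
            )
        if not abs(self.ld_rho) < 1:
            raise ValueError("|ld_rho| must be < 1")
        if self.exposure_se <= 0 or self.outcome_se <= 0:
            raise ValueError("standard errors must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class GwasPair:
    """Harmonizable exposure/outcome summary statistics with LD and truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    truth: dict


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def simulate_gwas_pair(params: GwasSimParams) -> GwasPair:
    """Draw an exposure/outcome GWAS pair with known causal effect.

    SNPs are placed every 50 kb on one chromosome; LD is AR(1) within
    consecutive blocks of ``ld_block_size`` SNPs and zero between blocks.
    The first SNP of each of the first ``n_instruments`` blocks is a true
    instrument.  The truth record stores the causal effect, the instrument
    ids and the per-SNP pleiotropy draws.
    """
    rng = np.random.default_rng(child_seed(params.seed, "gwas"))
    m = params.n_snps
    snp = [f"rs{i:06d}" for i in range(1, m + 1)]
    pos = (np.arange(m) + 1) * 50_000
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]
    eaf = rng.uniform(*params.maf_range, m)

    beta_true = np.zeros(m)
    inst_idx = np.arange(params.n_instruments) * params.ld_block_size
    beta_true[inst_idx] = rng.uniform(0.08, 0.25, params.n_instruments)

    beta_exp = beta_true + rng.normal(0.0, params.exposure_se, m)
    se_exp = np.full(m, params.exposure_se)
    p_exp = 2 * stats.norm.sf(np.abs(beta_exp / se_exp))

    pleiotropy = (
        rng.normal(params.pleiotropy_mean, params.pleiotropy_sd, m)
        if (params.pleiotropy_mean or params.pleiotropy_sd)
        else np.zeros(m)
    )
    beta_out = (
        params.true_effect * beta_true + pleiotropy
        + rng.normal(0.0, params.outcome_se, m)
    )
    se_out = np.full(m, params.outcome_se)
    p_out = 2 * stats.norm.sf(np.abs(beta_out / se_out))

    def frame(beta, se, pval):
        return pd.DataFrame(
            {
                "snp": snp,
                "chr": 1,
                "pos": pos,
                "effect_allele": [a for a, _ in pairs],
                "other_allele": [b for _, b in pairs],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": pval,
            }
        )

    n_blocks = int(np.ceil(m / params.ld_block_size))
    ld = np.zeros((m, m))
    for b in range(n_blocks):
        lo = b * params.ld_block_size
        hi = min(lo + params.ld_block_size, m)
        idx = np.arange(lo, hi)
        lag = np.abs(idx[:, None] - idx[None, :])
        ld[np.ix_(idx, idx)] = params.ld_rho**lag
    np.fill_diagonal(ld, 1.0)
    ld_df = pd.DataFrame(ld, index=snp, columns=snp)

    truth = {
        "true_effect": params.true_effect,
        "instruments": [snp[i] for i in inst_idx],
        "pleiotropy": {snp[i]: float(pleiotropy[i]) for i in inst_idx},
    }
    return GwasPair(exposure=frame(beta_exp, se_exp, p_exp),
                    outcome=frame(beta_out, se_out, p_out),
                    ld=ld_df, truth=truth)
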