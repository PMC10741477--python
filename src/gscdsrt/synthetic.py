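"""Synthetic cohort generator with known ground truth.

Emulates the study design the analysis assumes: 7 "multiregional" glioma
stem cell (GSC) cultures sampled from one tumor plus 14 independent reference
cultures from other patients, screened against 115 drugs in a five-point
dose-escalating viability assay, and an RNA-seq TPM matrix whose per-gene
log standard deviations follow a two-component mixture (homogeneously vs
heterogeneously expressed genes).

Drug-response ground truth is planted on the DSS scale: each drug gets a
cohort-level mean response, the multiregional cultures share one tumor-level
offset and scatter around it with the (small) intra-tumor SD, and reference
cultures scatter with the (larger) inter-tumor SD. A 4PL curve reproducing
each target DSS exactly is then constructed by solving for the IC50, so the
planted intra/inter variance structure is exact on the score scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import LogisticFit, compute_dss, logistic4


# ---------------------------------------------------------------------------
# Screen design and truth configuration
# ---------------------------------------------------------------------------

@dataclass
class ScreenDesign:
    """Cohort and plate layout of the simulated screen.

    Doses form a geometric (log-equispaced) series from ``dose_range[0]`` to
    ``dose_range[1]`` µM, mirroring the 0.4–250 µM five-point escalation.
    """

    n_multiregional: int = 7
    n_reference: int = 14
    n_drugs: int = 115
    doses_per_drug: int = 5
    dose_range: tuple[float, float] = (0.4, 250.0)
    replicate_wells: int = 1
    n_neg_ctrl: int = 16
    n_pos_ctrl: int = 8

    def __post_init__(self):
        for name in ("n_multiregional", "n_reference", "n_drugs",
                     "doses_per_drug", "replicate_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.dose_range
        if not (0 < lo < hi):
            raise ValueError("dose range must satisfy 0 < min < max")

    def doses(self) -> np.ndarray:
        lo, hi = self.dose_range
        return np.geomspace(lo, hi, self.doses_per_drug)

    @property
    def multiregional_ids(self) -> list[str]:
        return [f"MR{i+1:02d}" for i in range(self.n_multiregional)]

    @property
    def reference_ids(self) -> list[str]:
        return [f"REF{i+1:02d}" for i in range(self.n_reference)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug{i+1:03d}" for i in range(self.n_drugs)]


@dataclass
class ScreenTruthConfig:
    """Ground-truth parameters for the drug screen.

    ``intra_sd`` / ``inter_sd`` are culture-to-culture SDs of the planted DSS
    within the multiregional group and across reference cultures; the study
    premise is intra < inter. Drug-level mean responses are gamma-distributed
    so most drugs are weakly active and a minority reach DSS ≥ 10 in at least
    one culture, matching the responder fraction seen in GSC panels.
    ``noise_cv`` is the multiplicative (log-normal) coefficient of variation
    of well-level luminescence.
    """

    intra_sd: float = 2.0
    inter_sd: float = 4.0
    drug_mean_shape: float = 1.2
    drug_mean_scale: float = 4.0
    noise_cv: float = 0.05
    neg_mean: float = 1.0e6
    pos_level: float = 0.0   # positive-control signal as a fraction of neg_mean
    dss_threshold: float = 10.0
    dss_variant: str = "dss2"
    max_dss: float = 49.0
    #: targets below this score count as inactive (flat zero-response curve)
    min_active_dss: float = 0.01


@dataclass
class ScreenTruth:
    """Planted 4PL parameters and implied DSS per culture × drug."""

    params: pd.DataFrame  # culture, group, drug, top, bottom, slope, ic50, dss_true
    dss: pd.DataFrame     # cultures × drugs true DSS
    config: ScreenTruthConfig
    seed: int

    @property
    def groups(self) -> pd.Series:
        g = self.params.drop_duplicates("culture").set_index("culture")["group"]
        return g.sort_index()


# ---------------------------------------------------------------------------
# DSS-targeted curve construction
# ---------------------------------------------------------------------------

def ic50_for_dss(
    target_dss: float,
    cmin: float,
    cmax: float,
    top: float = 100.0,
    slope: float = 1.0,
    threshold: float = 10.0,
    variant: str = "dss2",
) -> float:
    """IC50 (µM) such that a (top, 0, slope, IC50) 4PL curve scores exactly
    ``target_dss`` over [cmin, cmax]. DSS is continuous and strictly
    decreasing in log10(IC50) wherever positive, so a 1-D root find suffices.
    """
    if target_dss <= 0:
        raise ValueError("target DSS must be positive; use top=0 for inactive drugs")
    xmin, xmax = math.log10(cmin), math.log10(cmax)

    def dss_at(L: float) -> float:
        fit = LogisticFit(top=top, bottom=0.0, slope=slope, ic50=10.0 ** L,
                          converged=True)
        return compute_dss(fit, cmin, cmax, threshold=threshold, variant=variant).dss

    lo, hi = xmin - 8.0, xmax + 8.0
    d_lo = dss_at(lo)
    if target_dss >= d_lo:
        raise ValueError(f"target DSS {target_dss} exceeds the maximum {d_lo:.3f} "
                         f"attainable with top={top}")
    L = brentq(lambda l: dss_at(l) - target_dss, lo, hi, xtol=1e-12)
    return 10.0 ** L


def make_dss_truth(
    design: ScreenDesign, config: ScreenTruthConfig, seed: int
) -> ScreenTruth:
    """Plant per culture × drug ground truth on the DSS scale and back out
    the 4PL parameters that realise it."""
    if config.intra_sd > config.inter_sd:
        warnings.warn(
            "intra-tumor SD exceeds inter-tumor SD: permitted (null "
            "simulation) but inverts the study premise"
        )
    rng = np.random.default_rng(seed)
    drug_means = rng.gamma(config.drug_mean_shape, config.drug_mean_scale,
                           size=design.n_drugs)
    tumor_offsets = rng.normal(0.0, config.inter_sd, size=design.n_drugs)

    cultures = design.multiregional_ids + design.reference_ids
    groups = (["multiregional"] * design.n_multiregional
              + ["reference"] * design.n_reference)
    cmin, cmax = design.dose_range

    rows = []
    dss_mat = pd.DataFrame(0.0, index=cultures, columns=design.drug_ids)
    for ci, (culture, group) in enumerate(zip(cultures, groups)):
        for di, drug in enumerate(design.drug_ids):
            if group == "multiregional":
                target = drug_means[di] + tumor_offsets[di] + rng.normal(0.0, config.intra_sd)
            else:
                target = drug_means[di] + rng.normal(0.0, config.inter_sd)
            target = float(np.clip(target, 0.0, config.max_dss))
            if target < config.min_active_dss:
                top, bottom, slope, ic50, dss_true = 0.0, 0.0, 1.0, float(cmax), 0.0
            else:
                top, bottom, slope = 100.0, 0.0, 1.0
                ic50 = ic50_for_dss(
                    target, cmin, cmax, top=top, slope=slope,
                    threshold=config.dss_threshold, variant=config.dss_variant,
                )
                dss_true = target
            rows.append((culture, group, drug, top, bottom, slope, ic50, dss_true))
            dss_mat.loc[culture, drug] = dss_true

    params = pd.DataFrame(
        rows, columns=["culture", "group", "drug", "top", "bottom", "slope",
                       "ic50", "dss_true"],
    )
    dss_mat.index.name = "culture"
    return ScreenTruth(params=params, dss=dss_mat, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Plate synthesis
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV; exactly 1 at cv=0."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def make_screen(
    design: ScreenDesign | None = None,
    truth_config: ScreenTruthConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], ScreenTruth]:
    """Simulate one plate per culture plus the ground truth behind it.

    Drug wells carry signal = neg_mean · (1 − inhibition(dose)/100) with
    multiplicative log-normal noise; negative (DMSO) and positive
    (full-kill) control wells are appended. With ``noise_cv = 0`` the plates
    are exact, so refitting recovers the planted curves.
    """
    design = design or ScreenDesign()
    truth_config = truth_config or ScreenTruthConfig()
    truth = make_dss_truth(design, truth_config, seed)

    well_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    doses = design.doses()
    neg_mean = truth_config.neg_mean
    pos_mean = truth_config.pos_level * neg_mean

    plates: dict[str, pd.DataFrame] = {}
    by_culture = truth.params.set_index(["culture", "drug"])
    for culture in truth.dss.index:
        recs = []
        for drug in design.drug_ids:
            p = by_culture.loc[(culture, drug)]
            inh = logistic4(np.log10(doses), p["top"], p["bottom"], p["slope"],
                            math.log10(p["ic50"]))
            for dose, y in zip(doses, inh):
                for _ in range(design.replicate_wells):
                    signal = neg_mean - (y / 100.0) * (neg_mean - pos_mean)
                    recs.append((drug, float(dose), "drug", signal))
        for _ in range(design.n_neg_ctrl):
            recs.append(("DMSO", 0.0, "neg_ctrl", neg_mean))
        for _ in range(design.n_pos_ctrl):
            recs.append(("benzethonium", 100.0, "pos_ctrl", pos_mean))
        plate = pd.DataFrame(recs, columns=["drug", "dose_uM", "well_type", "signal"])
        plate["signal"] *= _lognormal_factors(well_rng, truth_config.noise_cv,
                                              len(plate))
        plate.insert(0, "culture", culture)
        plates[culture] = plate
    return plates, truth


# ---------------------------------------------------------------------------
# Expression matrix synthesis
# ---------------------------------------------------------------------------

@dataclass
class MixtureConfig:
    """Two-component mixture on the natural-log SD scale of TPM, plus the
    planted QC failure modes the gene filters must catch.

    Defaults give 10% heterogeneous genes with component means 8 pooled SDs
    apart, a few percent of QC-failed genes, all-zero genes, and lowly
    expressed genes (mean TPM < 1).
    """

    mean_low: float = 0.0
    sd_low: float = 0.5
    mean_high: float = 4.0
    sd_high: float = 0.5
    weight_high: float = 0.1
    frac_failed: float = 0.02
    frac_all_zero: float = 0.05
    frac_low_expr: float = 0.10
    #: per-gene coefficient of variation range; each gene's mean TPM is its
    #: true SD divided by a CV drawn here, keeping tails moderate so the
    #: cross-sample SD is estimable from a handful of samples
    cv_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self):
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValueError("weight_high must be in [0, 1]")
        for name in ("frac_failed", "frac_all_zero", "frac_low_expr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass
class ExpressionTruth:
    genes: pd.DataFrame  # gene, label, true_mean, true_sd, planted flags
    config: MixtureConfig
    seed: int


def make_expression(
    n_genes: int = 5000,
    n_samples: int = 7,
    mix_config: MixtureConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Genes × samples TPM matrix with a planted dispersion mixture.

    Per gene, a component label (homogeneous/heterogeneous) is drawn with
    weight ``weight_high``, a true cross-sample SD is drawn from that
    component on the log-SD scale, and TPM values are sampled log-normally
    around the gene's true mean with that SD. Failed, all-zero and
    low-expression genes are planted to exercise the filters. Returns the
    matrix (with a ``qc_flag`` column) and the ground truth.
    """
    cfg = mix_config or MixtureConfig()
    rng = np.random.default_rng(seed)
    genes = [f"gene{i+1:05d}" for i in range(n_genes)]
    samples = [f"S{j+1:02d}" for j in range(n_samples)]

    is_het = rng.random(n_genes) < cfg.weight_high
    log_sd = np.where(
        is_het,
        rng.normal(cfg.mean_high, cfg.sd_high, n_genes),
        rng.normal(cfg.mean_low, cfg.sd_low, n_genes),
    )
    true_sd = np.exp(log_sd)

    is_failed = rng.random(n_genes) < cfg.frac_failed
    is_zero = rng.random(n_genes) < cfg.frac_all_zero
    is_low = rng.random(n_genes) < cfg.frac_low_expr
    # mean TPM follows from the planted SD at a moderate CV (variable genes
    # are more highly expressed, as in real TPM data); planted low-expression
    # genes get mean < 1 with their SD rescaled to keep the same CV
    cv = rng.uniform(cfg.cv_range[0], cfg.cv_range[1], n_genes)
    mean_tpm = true_sd / cv
    low_means = rng.uniform(0.01, 0.99, n_genes)
    true_sd = np.where(is_low, low_means * cv, true_sd)
    log_sd = np.log(true_sd)
    mean_tpm = np.where(is_low, low_means, mean_tpm)

    tpm = np.zeros((n_genes, n_samples))
    for i in range(n_genes):
        if is_zero[i]:
            continue
        m, s = mean_tpm[i], true_sd[i]
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        tpm[i] = rng.lognormal(mu, math.sqrt(sigma2), n_samples)

    matrix = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"), columns=samples)
    matrix["qc_flag"] = np.where(is_failed, "failed", "ok")

    truth = pd.DataFrame({
        "gene": genes,
        "label": np.where(is_het, "heterogeneous", "homogeneous"),
        "true_mean": mean_tpm,
        "true_sd": true_sd,
        "true_log_sd": log_sd,
        "planted_failed": is_failed,
        "planted_all_zero": is_zero,
        "planted_low_expr": is_low,
    }).set_index("gene")
    return matrix, ExpressionTruth(genes=truth, config=cfg, seed=seed)


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------

def write_plates(plates: dict[str, pd.DataFrame], path) -> None:
    """Concatenate all plates into one long-format TSV."""
    pd.concat(plates.values(), ignore_index=True).to_csv(path, sep="\t", index=False)


def read_plates(path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t", comment="#")
    return {str(c): g.reset_index(drop=True) for c, g in long.groupby("culture", sort=True)}


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
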