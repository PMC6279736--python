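"""Probe QC, covariate normalisation of β-values, and outlier handling.

Probes on sex chromosomes, multi-mapping (blacklisted) probes, non-CpG
probes, and probes with excess missingness or detection failure are removed
before association. β-values are then normalised per probe with a
logistic-link quasi-binomial fit against the technical and biological
covariates (chip, chip position, sex, age, age², interactions, optionally
cell counts), and the link-scale residual is the phenotype passed to the
association scan. Outlying measurements more than five interquartile ranges
from their nearest quartile are either removed (discovery-cohort rule) or
trigger MAF-restricted testing for the probe (replication-cohort rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import logit

from mqtlkit.containers import MethylationMatrix

logger = logging.getLogger(__name__)

SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24"}
BETA_EPS = 1e-6


@dataclass
class ProbeQcConfig:
    drop_sex_chroms: bool = True
    drop_multimapping: bool = True
    drop_non_cpg: bool = True
    max_missing_fraction: float = 0.05
    max_detection_fail_fraction: float = 0.05
    iqr_multiplier: float = 5.0

    def __post_init__(self) -> None:
        for frac in (self.max_missing_fraction, self.max_detection_fail_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("QC fractions must lie in [0, 1]")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be positive")


def filter_probes(
    meth: MethylationMatrix,
    qc: ProbeQcConfig,
    blacklist: set[str] | None = None,
    detection_fail: np.ndarray | None = None,
) -> MethylationMatrix:
    """Drop probes failing any QC rule; per-reason counts are logged.

    ``detection_fail`` is an optional probes × samples boolean matrix of
    detection-p ≥ 0.001 failures. Idempotent: a second application removes
    nothing further.
    """
    blacklist = blacklist or set()
    probes = meth.probes
    n = meth.n_probes
    drop_sex = (
        probes["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
        if qc.drop_sex_chroms
        else np.zeros(n, dtype=bool)
    )
    drop_multi = (
        probes["probe_id"].isin(blacklist).to_numpy()
        if qc.drop_multimapping
        else np.zeros(n, dtype=bool)
    )
    if qc.drop_non_cpg and "is_cpg" in probes.columns:
        drop_noncpg = ~probes["is_cpg"].fillna(True).to_numpy(dtype=bool)
    else:
        drop_noncpg = np.zeros(n, dtype=bool)
    missing_frac = np.mean(~np.isfinite(meth.beta), axis=1)
    drop_missing = missing_frac > qc.max_missing_fraction
    if detection_fail is not None:
        fail_frac = np.mean(np.asarray(detection_fail, dtype=bool), axis=1)
        drop_detect = fail_frac > qc.max_detection_fail_fraction
    else:
        drop_detect = np.zeros(n, dtype=bool)
    drop = drop_sex | drop_multi | drop_noncpg | drop_missing | drop_detect
    logger.info(
        "probe QC: %d/%d retained (sex %d, multimap %d, non-CpG %d, missing %d, detection %d)",
        (~drop).sum(), n, drop_sex.sum(), drop_multi.sum(), drop_noncpg.sum(),
        drop_missing.sum(), drop_detect.sum(),
    )
    if drop.all():
        warnings.warn("probe QC removed every probe", stacklevel=2)
    return meth.subset_probes(~drop)


def normalize_probe(beta_row: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Normalise one probe's β-values against a covariate design matrix.

    Fits a logistic-link quasi-binomial GLM of β on the covariates and
    returns link-scale (logit) residuals projected onto the orthogonal
    complement of the design, so the output has exactly zero sample
    correlation with every covariate column. With an intercept-only design
    this reduces to centred logit(β). β equal to 0 or 1 is clipped to
    [ε, 1−ε] with ε = 1e-6 (count logged). Missing values pass through as
    NaN; the fit uses complete cases only.
    """
    y = np.asarray(beta_row, dtype=float)
    out = np.full(y.shape, np.nan)
    obs = np.isfinite(y)
    yo = y[obs]
    n_clip = int(np.sum((yo <= 0) | (yo >= 1)))
    if n_clip:
        logger.info("normalize_probe: clipped %d boundary β-values", n_clip)
    yo = np.clip(yo, BETA_EPS, 1 - BETA_EPS)
    if covariates is None:
        x = np.ones((yo.size, 1))
    else:
        x = np.asarray(covariates, dtype=float)[obs]
        if x.ndim == 1:
            x = x[:, None]
        has_const = bool(np.any(np.ptp(x, axis=0) == 0))
        if not has_const:
            x = np.column_stack([np.ones(yo.size), x])
    eta = logit(yo)
    if np.ptp(yo) == 0:
        out[obs] = 0.0
        return out
    if x.shape[1] == 1 and np.ptp(x) == 0:
        # intercept-only design: the projection reduces to centring, no fit needed
        out[obs] = eta - eta.mean()
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(yo, x, family=sm.families.Binomial()).fit()
            resid = eta - fit.predict(x, which="linear")
        except Exception:  # pragma: no cover - singular designs
            resid = eta
    # project out the design exactly: residual correlation with every
    # covariate column is 0 to machine precision
    coef, *_ = np.linalg.lstsq(x, resid, rcond=None)
    resid = resid - x @ coef
    out[obs] = resid
    return out


def normalize_matrix(
    meth: MethylationMatrix,
    covariates: np.ndarray | None,
    groups: np.ndarray | None = None,
) -> MethylationMatrix:
    """Normalise every probe; ``groups`` normalises sample groups separately
    (sub-cohorts first, then combined), mirroring per-cohort normalisation."""
    norm = np.full(meth.beta.shape, np.nan)
    if groups is None:
        group_masks = [np.ones(meth.n_samples, dtype=bool)]
    else:
        groups = np.asarray(groups)
        group_masks = [groups == g for g in np.unique(groups)]
    for mask in group_masks:
        cov = None if covariates is None else np.asarray(covariates)[mask]
        for i in range(meth.n_probes):
            norm[i, mask] = normalize_probe(meth.beta[i, mask], cov)
    out = MethylationMatrix.__new__(MethylationMatrix)
    out.probes = meth.probes.copy().reset_index(drop=True)
    out.samples = list(meth.samples)
    out.beta = norm  # link-scale residuals, no longer bounded to [0, 1]
    return out


def remove_outliers(
    values: np.ndarray,
    iqr_multiplier: float = 5.0,
    mode: str = "remove",
) -> tuple[np.ndarray, np.ndarray]:
    """Flag values beyond ``iqr_multiplier`` IQRs from the nearest quartile.

    Quartiles use linear interpolation (type 7). ``mode="remove"`` sets
    outliers to NaN; ``mode="restrict_maf"`` leaves values intact (the caller
    restricts the probe to common SNPs instead). Returns
    ``(values, outlier_flags)``. With IQR = 0 the fences collapse onto the
    quartiles and any deviating value is flagged as degenerate.
    """
    if mode not in ("remove", "restrict_maf"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.asarray(values, dtype=float).copy()
    obs = np.isfinite(vals)
    if obs.sum() < 4:
        raise ValueError("need at least 4 non-missing values")
    q1, q3 = np.percentile(vals[obs], [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    flags = np.zeros(vals.shape, dtype=bool)
    flags[obs] = (vals[obs] < lo) | (vals[obs] > hi)
    if iqr == 0 and flags.any():
        logger.warning("remove_outliers: degenerate distribution (IQR = 0)")
    if mode == "remove":
        vals[flags] = np.nan
    return vals, flags


def apply_outlier_policy(
    meth: MethylationMatrix, iqr_multiplier: float = 5.0, mode: str = "remove"
) -> MethylationMatrix:
    """Apply the 5-IQR rule to every probe row of a (normalised) matrix.

    In ``restrict_maf`` mode, probes with any outlier get
    ``restrict_maf=True`` in the probe metadata and their values are kept.
    """
    beta = meth.beta.copy()
    probes = meth.probes.copy()
    if "restrict_maf" not in probes.columns:
        probes["restrict_maf"] = False
    for i in range(meth.n_probes):
        if np.isfinite(beta[i]).sum() < 4:
            continue
        vals, flags = remove_outliers(beta[i], iqr_multiplier, mode)
        beta[i] = vals
        if mode == "restrict_maf" and flags.any():
            probes.loc[i, "restrict_maf"] = True
    out = MethylationMatrix.__new__(MethylationMatrix)
    out.probes = probes.reset_index(drop=True)
    out.samples = list(meth.samples)
    out.beta = beta
    return out


__all__ = [
    "ProbeQcConfig",
    "apply_outlier_policy",
    "filter_probes",
    "normalize_matrix",
    "normalize_probe",
    "remove_outliers",
]
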