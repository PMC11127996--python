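"""QC filtering, missing-value imputation and the normalization cascade.

An intensity matrix is lipids (rows) x samples (columns).  Sample metadata is
a DataFrame indexed by sample id with columns ``region_id``,
``individual_id``, ``sample_type`` (tissue / QC / blank / extraction_blank /
LTR / DiQC), ``wet_weight_mg``, ``batch_id`` and, for DiQC samples,
``dilution_factor``.

Stage order: raw -> imputed -> filtered -> normalized.  Every operation
appends a provenance record so a run can be replayed step by step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IntensityMatrix",
    "impute_missing",
    "blank_filter",
    "qc_cv_filter",
    "mrm_qc_filter",
    "normalize_intensities",
    "normalize_expression",
    "replay",
]

_BLANK_TYPES = ("blank", "extraction_blank")
_STAGES = ("raw", "imputed", "filtered", "log", "normalized")


@dataclass
class IntensityMatrix:
    """Lipids x samples abundance table with a processing-stage tag."""

    data: pd.DataFrame
    stage: str = "raw"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _advance(self, stage: str, step: str, **params) -> "IntensityMatrix":
        if _STAGES.index(stage) < _STAGES.index(self.stage):
            raise ValueError(
                f"stage transition {self.stage} -> {stage} violates "
                "pipeline order"
            )
        return IntensityMatrix(
            data=self.data,
            stage=stage,
            provenance=self.provenance + [{"step": step, **params}],
        )


def _tissue_samples(meta: pd.DataFrame) -> pd.Index:
    return meta.index[meta["sample_type"] == "tissue"]


def impute_missing(matrix: IntensityMatrix, seed: int) -> IntensityMatrix:
    """Fill missing intensities by sampling a left-tail normal model.

    Missing entries (NaN or 0) are drawn from Normal(mu, sigma) truncated at
    zero, where, over the distribution D of per-lipid minimal detected
    intensities, mu = median(D) and sigma = the 16th percentile of D.  Draws
    are seeded and reproducible.
    """
    x = matrix.data.to_numpy(dtype=float).copy()
    missing = ~(np.isfinite(x) & (x > 0))
    detected_min = np.where(missing, np.inf, x).min(axis=1)
    dead = ~np.isfinite(detected_min)
    if dead.any():
        name = matrix.data.index[np.flatnonzero(dead)[0]]
        raise ValueError(f"lipid {name!r} has no detected values")
    if missing.any():
        mu = float(np.median(detected_min))
        sigma = float(np.percentile(detected_min, 16))
        rng = np.random.default_rng(seed)
        a = (0.0 - mu) / sigma
        fills = sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                                  size=int(missing.sum()), random_state=rng)
        x[missing] = fills
    out = matrix._advance("imputed", "impute_missing", seed=seed,
                          n_filled=int(missing.sum()))
    out.data = pd.DataFrame(x, index=matrix.data.index,
                            columns=matrix.data.columns)
    return out


def blank_filter(matrix: IntensityMatrix, meta: pd.DataFrame,
                 factor: float = 2.0) -> IntensityMatrix:
    """Keep lipids whose mean tissue intensity is >= factor x mean blank."""
    blanks = meta.index[meta["sample_type"].isin(_BLANK_TYPES)]
    if len(blanks) == 0:
        raise ValueError("blank_filter requires at least one blank sample")
    tissue = _tissue_samples(meta)
    mt = matrix.data[tissue].mean(axis=1)
    mb = matrix.data[blanks].mean(axis=1)
    keep = mt >= factor * mb
    out = matrix._advance("filtered", "blank_filter", factor=factor,
                          n_removed=int((~keep).sum()))
    out.data = matrix.data.loc[keep]
    return out


def qc_cv_filter(matrix: IntensityMatrix, meta: pd.DataFrame,
                 max_cv: float = 0.25) -> IntensityMatrix:
    """Keep lipids whose median per-batch QC coefficient of variation is
    below ``max_cv`` (CoV computed on the raw scale)."""
    qc = meta[meta["sample_type"] == "QC"]
    cvs = []
    for batch, grp in qc.groupby("batch_id"):
        if len(grp) < 2:
            warnings.warn(
                f"batch {batch!r} has <2 QC samples, excluded from the "
                "median CoV", stacklevel=2)
            continue
        sub = matrix.data[grp.index]
        cvs.append(sub.std(axis=1, ddof=1) / sub.mean(axis=1))
    if not cvs:
        raise ValueError("no batch with >=2 QC samples")
    median_cv = pd.concat(cvs, axis=1).median(axis=1)
    keep = median_cv < max_cv
    out = matrix._advance("filtered", "qc_cv_filter", max_cv=max_cv,
                          n_removed=int((~keep).sum()))
    out.data = matrix.data.loc[keep]
    return out


def mrm_qc_filter(matrix: IntensityMatrix, meta: pd.DataFrame,
                  blank_ratio: float = 0.1, max_cv: float = 0.25,
                  min_diqc_r: float = 0.9) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Three-way QC filter for targeted (MRM) transitions.

    A transition is kept iff (1) mean blank intensity does not exceed
    ``blank_ratio`` of the mean intensity in real samples, (2) its QC-sample
    coefficient of variation is <= ``max_cv``, and (3) the Pearson correlation
    between log intensity and log dilution factor across the DiQC dilution
    series is >= ``min_diqc_r``.  When no DiQC samples exist the third test is
    skipped and flagged.

    Returns the filtered matrix plus a per-transition report of the three
    test outcomes.
    """
    tissue = _tissue_samples(meta)
    blanks = meta.index[meta["sample_type"].isin(_BLANK_TYPES)]
    qcs = meta.index[meta["sample_type"] == "QC"]
    diqc = meta[meta["sample_type"] == "DiQC"]
    if len(blanks) == 0 or len(qcs) < 2:
        raise ValueError("mrm_qc_filter needs blanks and >=2 QC samples")

    mt = matrix.data[tissue].mean(axis=1)
    pass_blank = matrix.data[blanks].mean(axis=1) <= blank_ratio * mt
    qc_sub = matrix.data[qcs]
    pass_cv = (qc_sub.std(axis=1, ddof=1) / qc_sub.mean(axis=1)) <= max_cv

    if len(diqc) >= 3:
        if (diqc["dilution_factor"] <= 0).any() or \
                (diqc["dilution_factor"] > 1).any():
            raise ValueError("DiQC dilution factors must lie in (0, 1]")
        logd = np.log10(diqc["dilution_factor"].to_numpy(dtype=float))
        logx = np.log10(matrix.data[diqc.index].to_numpy(dtype=float))
        xc = logx - logx.mean(axis=1, keepdims=True)
        dc = logd - logd.mean()
        denom = np.sqrt((xc ** 2).sum(axis=1) * (dc ** 2).sum())
        with np.errstate(invalid="ignore"):
            r = (xc @ dc) / denom
        pass_diqc = pd.Series(r >= min_diqc_r, index=matrix.data.index)
        diqc_skipped = False
    else:
        warnings.warn("no DiQC dilution series; linearity test skipped",
                      stacklevel=2)
        pass_diqc = pd.Series(True, index=matrix.data.index)
        diqc_skipped = True

    report = pd.DataFrame({
        "pass_blank": pass_blank,
        "pass_cv": pass_cv,
        "pass_diqc": pass_diqc,
        "diqc_skipped": diqc_skipped,
    })
    keep = pass_blank & pass_cv & pass_diqc
    out = matrix._advance("filtered", "mrm_qc_filter",
                          blank_ratio=blank_ratio, max_cv=max_cv,
                          min_diqc_r=min_diqc_r,
                          n_removed=int((~keep).sum()))
    out.data = matrix.data.loc[keep]
    return out, report


def normalize_intensities(matrix: IntensityMatrix, meta: pd.DataFrame,
                          standards_medians: pd.Series) -> IntensityMatrix:
    """Log-transform and normalize tissue intensities.

    For tissue sample j with log10 standards-median s_j and log10 wet weight
    w_j:  x' = log10(x) - (s_j - mean(s)) - (w_j - mean(w)).  Then, per lipid
    and per individual, the mean over that individual's regions is subtracted,
    so per-(lipid, individual) means are exactly zero afterward.  Non-tissue
    samples are dropped.
    """
    tissue = _tissue_samples(meta)
    if len(tissue) == 0:
        raise ValueError("no tissue samples to normalize")
    x = matrix.data[tissue].to_numpy(dtype=float)
    if not np.isfinite(x).all() or (x <= 0).any():
        raise ValueError("nonpositive or missing intensity at log step; "
                         "impute first")
    weights = meta.loc[tissue, "wet_weight_mg"].to_numpy(dtype=float)
    if not np.isfinite(weights).all() or (weights <= 0).any():
        bad = tissue[~(np.isfinite(weights) & (weights > 0))][0]
        raise ValueError(f"tissue sample {bad!r} has no valid wet weight")
    s = np.log10(standards_medians.loc[tissue].to_numpy(dtype=float))
    w = np.log10(weights)
    logx = np.log10(x) - (s - s.mean()) - (w - w.mean())
    df = pd.DataFrame(logx, index=matrix.data.index, columns=tissue)
    indiv = meta.loc[tissue, "individual_id"]
    for ind, cols in indiv.groupby(indiv).groups.items():
        df[list(cols)] = df[list(cols)].sub(df[list(cols)].mean(axis=1),
                                            axis=0)
    out = matrix._advance("normalized", "normalize_intensities")
    out.data = df
    return out


def normalize_expression(tpm: pd.DataFrame, meta: pd.DataFrame,
                         protein_coding: pd.Series | None = None,
                         min_tpm: float = 1.0,
                         floor: float = 1e-2) -> pd.DataFrame:
    """TPM gate, log transform and centering for marker gene expression.

    Keeps protein-coding genes with TPM > ``min_tpm`` in at least one sample;
    log10-transforms (zeros floored at ``floor``); subtracts each sample's
    median deviation from the grand mean of sample medians; then centers each
    gene per individual.
    """
    if (tpm < 0).to_numpy().any():
        raise ValueError("TPM values must be nonnegative")
    x = tpm
    if protein_coding is not None:
        x = x.loc[protein_coding.reindex(x.index, fill_value=False)]
    x = x.loc[(x > min_tpm).any(axis=1)]
    logx = np.log10(x.clip(lower=floor))
    med = logx.median(axis=0)
    logx = logx.sub(med - med.mean(), axis=1)
    indiv = meta.loc[logx.columns, "individual_id"]
    for ind, cols in indiv.groupby(indiv).groups.items():
        logx[list(cols)] = logx[list(cols)].sub(
            logx[list(cols)].mean(axis=1), axis=0)
    return logx


_REPLAY_STEPS = {
    "impute_missing": lambda m, meta, std, p: impute_missing(m, p["seed"]),
    "blank_filter": lambda m, meta, std, p: blank_filter(m, meta, p["factor"]),
    "qc_cv_filter": lambda m, meta, std, p: qc_cv_filter(m, meta, p["max_cv"]),
    "normalize_intensities":
        lambda m, meta, std, p: normalize_intensities(m, meta, std),
}


def replay(raw: IntensityMatrix, meta: pd.DataFrame,
           standards_medians: pd.Series | None,
           provenance: list[dict]) -> IntensityMatrix:
    """Re-apply a provenance log to a raw matrix; bit-for-bit reproducible
    given the recorded seeds."""
    m = raw
    for rec in provenance:
        step = rec["step"]
        if step not in _REPLAY_STEPS:
            raise ValueError(f"cannot replay step {step!r}")
        m = _REPLAY_STEPS[step](m, meta, standards_medians, rec)
    return m
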