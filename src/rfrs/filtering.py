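"""Probe/gene filtering for model input, and reference-gene selection.

All thresholds operate on linear-scale intensities: the background
threshold (raw value > 100) and the coefficient-of-variation window
(0.7-10) are only meaningful before log transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InputError

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    background_threshold: float = 100.0
    min_expressed_fraction: float = 0.20
    cov_min: float = 0.7
    cov_max: float = 10.0

    def validate(self) -> None:
        if not self.cov_min < self.cov_max:
            raise InputError("cov_min must be < cov_max")
        if not 0 <= self.min_expressed_fraction <= 1:
            raise InputError("min_expressed_fraction must be in [0, 1]")


def _cov(values: pd.DataFrame) -> pd.Series:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return sd / mean


def filter_features(expr: ExpressionMatrix, cfg: FilterConfig | None = None) -> list[str]:
    """Retain features expressed above background in at least
    ``min_expressed_fraction`` of samples with coefficient of variation
    (sd/mean, linear scale) inside [cov_min, cov_max]."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    v = expr.values
    frac = (v > cfg.background_threshold).mean(axis=0)
    cov = _cov(v)
    keep = (frac >= cfg.min_expressed_fraction) & (cov >= cfg.cov_min) & (cov <= cfg.cov_max)
    return list(v.columns[keep.fillna(False)])


def select_reference_genes_global(
    expr: ExpressionMatrix,
    background_threshold: float = 100.0,
    expressed_fraction: float = 0.99,
    mean_percentile: float = 95.0,
    sd_percentile: float = 90.0,
    top_n: int = 25,
    sd_top: bool = True,
) -> list[str]:
    """Global reference-gene panel for platform migration.

    In order: (1) keep features expressed above background in at least
    ``expressed_fraction`` of samples; (2) keep only the top 5th
    percentile by mean; (3) keep only the top 10th percentile (of the
    remainder) by standard deviation; (4) rank survivors by coefficient
    of variation ascending and return the ``top_n`` most stable.

    The top-SD step is applied exactly as specified; pass
    ``sd_top=False`` to keep the bottom percentile instead (the more
    conventional choice for invariant reference genes).
    """
    if expr.n_samples < 100:
        logger.warning("reference-gene selection on only %d samples", expr.n_samples)
    v = expr.values
    frac = (v > background_threshold).mean(axis=0)
    step1 = v.loc[:, frac >= expressed_fraction]
    if step1.shape[1] == 0:
        logger.warning("no features expressed in >= %.0f%% of samples", 100 * expressed_fraction)
        return []
    means = step1.mean(axis=0)
    step2 = step1.loc[:, means >= np.percentile(means, mean_percentile)]
    sds = step2.std(axis=0, ddof=1)
    if sd_top:
        step3 = step2.loc[:, sds >= np.percentile(sds, sd_percentile)]
    else:
        step3 = step2.loc[:, sds <= np.percentile(sds, 100 - sd_percentile)]
    if step3.shape[1] == 0:
        logger.warning("no reference-gene survivors after percentile filters")
        return []
    cov = _cov(step3).sort_values(kind="stable")
    return list(cov.index[:top_n])


#: closed mean-intensity bands spanning the signature genes' range
DEFAULT_BANDS = {"low": (0.0, 400.0), "medium": (500.0, 900.0), "high": (1200.0, 1600.0)}


def select_reference_genes_banded(
    expr: ExpressionMatrix,
    bands: dict[str, tuple[float, float]] | None = None,
    background_threshold: float = 100.0,
    expressed_fraction: float = 0.99,
    top_n: int = 5,
) -> dict[str, list[str]]:
    """Banded reference panel: per mean-expression band (closed
    intervals), keep features expressed above background in at least
    ``expressed_fraction`` of samples, rank by coefficient of variation
    ascending, return the top ``top_n`` per band."""
    bands = bands or DEFAULT_BANDS
    v = expr.values
    frac = (v > background_threshold).mean(axis=0)
    expressed = v.loc[:, frac >= expressed_fraction]
    means = expressed.mean(axis=0)
    out: dict[str, list[str]] = {}
    for name, (lo, hi) in bands.items():
        in_band = expressed.loc[:, (means >= lo) & (means <= hi)]
        if in_band.shape[1] == 0:
            logger.warning("reference band %r (%g-%g) is empty", name, lo, hi)
            out[name] = []
            continue
        cov = _cov(in_band).sort_values(kind="stable")
        out[name] = list(cov.index[:top_n])
    return out
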