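"""Probe filtering ahead of methylation deconvolution.

Probes are removed for (a) any missing beta value, (b) location on a sex
chromosome, (c) membership in user-supplied blocklists (mask files consumed
as plain probe-ID lists), and (d) association with sample covariates at a
given false-discovery rate.  Filters are pure set restrictions, so their
order does not change the result; a log records counts removed per
criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class FilterLog:
    """Per-criterion counts of removed probes."""

    n_input: int = 0
    n_missing: int = 0
    n_sex_chromosome: int = 0
    n_blocklisted: int = 0
    n_covariate_associated: int = 0
    n_output: int = 0
    skipped_covariates: list[str] = field(default_factory=list)


def load_blocklist(path: str | Path) -> set[str]:
    """Read a plain-text blocklist, one probe ID per line."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def filter_probes(
    meth: pd.DataFrame,
    blocklists: Iterable[Iterable[str]] = (),
    drop_missing: bool = True,
    drop_sex_chromosomes: bool = False,
    chromosomes: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """Restrict a probes x samples beta matrix to probes passing all filters.

    ``chromosomes`` maps probe ID to chromosome name and is required when
    ``drop_sex_chromosomes`` is set.  The input is never mutated.  Raises if
    no probes remain.
    """
    log = FilterLog(n_input=meth.shape[0])
    keep = pd.Series(True, index=meth.index)

    if drop_missing:
        missing = meth.isna().any(axis=1)
        log.n_missing = int(missing.sum())
        keep &= ~missing

    if drop_sex_chromosomes:
        if chromosomes is None:
            raise ValueError("drop_sex_chromosomes requires a probe -> chromosome mapping")
        chrom = pd.Series(chromosomes)
        on_sex = meth.index.to_series().map(chrom).isin(SEX_CHROMOSOMES)
        log.n_sex_chromosome = int(on_sex.sum())
        keep &= ~on_sex

    blocked: set[str] = set()
    for bl in blocklists:
        blocked |= set(bl)
    if blocked:
        in_block = meth.index.to_series().isin(blocked)
        log.n_blocklisted = int(in_block.sum())
        keep &= ~in_block

    out = meth.loc[keep].copy()
    log.n_output = out.shape[0]
    if out.shape[0] == 0:
        raise ValueError("no probes remain after filtering")
    logger.info(
        "probe filtering: %d -> %d (missing %d, sex-chromosome %d, blocklisted %d)",
        log.n_input, log.n_output, log.n_missing, log.n_sex_chromosome, log.n_blocklisted,
    )
    return out, log


def _anova_pvalues(B: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-way ANOVA F-test per probe (rows of B), vectorized over probes."""
    levels = np.unique(groups)
    n = B.shape[1]
    k = len(levels)
    grand = B.mean(axis=1)
    ss_between = np.zeros(B.shape[0])
    ss_within = np.zeros(B.shape[0])
    for lv in levels:
        sel = groups == lv
        m = B[:, sel].mean(axis=1)
        ss_between += sel.sum() * (m - grand) ** 2
        ss_within += ((B[:, sel] - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(F, df1, df2)
    return np.where(np.isfinite(F), p, 1.0)


def _slope_pvalues(B: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Simple linear regression slope t-test per probe, vectorized."""
    n = B.shape[1]
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    yc = B - B.mean(axis=1, keepdims=True)
    beta = (yc @ xc) / sxx
    rss = (yc**2).sum(axis=1) - beta**2 * sxx
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isfinite(t), p, 1.0)


def filter_probes_by_covariates(
    meth: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterLog]:
    """Remove probes associated with any sample covariate at the given FDR.

    Categorical covariates (non-numeric dtype) are tested per probe with a
    one-way ANOVA F-test; continuous covariates with a simple linear
    regression slope t-test.  P-values are Benjamini-Hochberg adjusted per
    covariate; probes below ``fdr_threshold`` for any covariate are removed.
    Samples missing a covariate value are dropped from that covariate's test
    only; constant covariates are skipped with a warning.
    """
    log = FilterLog(n_input=meth.shape[0])
    if covariates is None or covariates.shape[1] == 0:
        log.n_output = meth.shape[0]
        return meth, log
    missing_samples = set(meth.columns) - set(covariates.index)
    if missing_samples:
        raise ValueError(f"covariate table lacks samples: {sorted(missing_samples)[:5]}")

    associated = pd.Series(False, index=meth.index)
    for name in covariates.columns:
        col = covariates.loc[list(meth.columns), name]
        ok = col.notna().to_numpy()
        values = col[ok]
        B = meth.to_numpy()[:, ok]
        is_numeric = pd.api.types.is_numeric_dtype(values)
        if values.nunique() < 2:
            warnings.warn(f"covariate {name!r} is constant across samples; skipped")
            log.skipped_covariates.append(name)
            continue
        if is_numeric:
            if not np.isfinite(values.to_numpy(dtype=float)).all():
                raise ValueError(f"continuous covariate {name!r} has non-finite values")
            if len(values) < 3:
                warnings.warn(f"covariate {name!r} has too few samples; skipped")
                log.skipped_covariates.append(name)
                continue
            p = _slope_pvalues(B, values.to_numpy(dtype=float))
        else:
            counts = values.value_counts()
            if (counts < 3).any():
                warnings.warn(
                    f"covariate {name!r} has levels with < 3 samples; skipped"
                )
                log.skipped_covariates.append(name)
                continue
            p = _anova_pvalues(B, values.to_numpy())
        q = bh_adjust(p)
        associated |= pd.Series(q < fdr_threshold, index=meth.index)

    log.n_covariate_associated = int(associated.sum())
    out = meth.loc[~associated].copy()
    log.n_output = out.shape[0]
    if out.shape[0] == 0:
        raise ValueError("no probes remain after covariate filtering")
    return out, log
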