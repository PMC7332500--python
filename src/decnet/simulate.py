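"""Synthetic reference panels and paired methylation/expression mixtures.

The simulator emulates the study design this package is tested on: a small
set of distinct cell-type methylation archetypes (e.g. immune, fibroblast,
epithelial, cancer), two cancer *variants* that share one methylation
archetype but differ in the expression of a single gene of interest, and
bulk mixtures formed by Dirichlet-random cell-type proportions that are
shared between a sample's methylation and expression columns ("matched"
mixing).  Ground truth (proportions, variant labels, seeds) is returned so
recovery can be scored exactly.

Conventions: rows are features (probes / genes), columns are samples,
everywhere in this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: name used for the cancer methylation archetype / expression columns
CANCER = "cancer"
#: suffixes of the two cancer expression variants
VARIANT_HI = "cancer_hi"
VARIANT_LO = "cancer_lo"

_NONCANCER_NAMES = ["stroma", "immune", "epithelial", "endothelial"]


@dataclass
class ReferencePanel:
    """Class-labeled reference methylation and expression profiles.

    ``meth_profiles`` has one column per methylation archetype (the two
    cancer variants share the ``cancer`` archetype); ``expr_profiles`` has
    one column per non-cancer class plus ``cancer_hi`` / ``cancer_lo``.
    """

    class_labels: list[str]
    meth_profiles: pd.DataFrame  # probes x classes, beta values in [0, 1]
    expr_profiles: pd.DataFrame  # genes x (classes - 1 + 2 variants), >= 0
    variant_gene: str
    variant_fold: float = 1.0

    def __post_init__(self) -> None:
        if len(self.class_labels) < 2:
            raise ValueError("a reference panel needs at least 2 classes")
        vals = self.meth_profiles.to_numpy()
        if not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 1:
            raise ValueError("methylation profiles must be finite beta values in [0, 1]")
        if (self.expr_profiles.to_numpy() < 0).any():
            raise ValueError("expression profiles must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.class_labels)

    @property
    def has_variants(self) -> bool:
        return VARIANT_HI in self.expr_profiles.columns

    def expr_for_variant(self, variant: str) -> pd.DataFrame:
        """Expression profiles (genes x k) with the cancer column taken from one variant."""
        cols = {}
        for label in self.class_labels:
            if label == CANCER and self.has_variants:
                cols[label] = self.expr_profiles[variant]
            else:
                cols[label] = self.expr_profiles[label]
        return pd.DataFrame(cols, index=self.expr_profiles.index)


@dataclass
class MixtureTruth:
    """Ground truth emitted alongside simulated mixtures."""

    P_true: pd.DataFrame  # cell types x samples, columns on the simplex
    assigned_variant: pd.Series  # sample -> variant column name
    noise_precision: float | None
    dirichlet_alpha: np.ndarray
    seed: int
    expression_noise: str = "none"

    def __post_init__(self) -> None:
        P = self.P_true.to_numpy()
        if (P < 0).any():
            raise ValueError("true proportions must be nonnegative")
        if np.max(np.abs(P.sum(axis=0) - 1.0)) > 1e-12:
            raise ValueError("true proportion columns must sum to 1")
        if not set(self.P_true.columns) <= set(self.assigned_variant.index):
            raise ValueError("assigned_variant must cover every sample")


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def generate_reference_panel(
    k: int,
    n_probes: int,
    n_genes: int,
    variant_fold: float = 10.0,
    seed: int = 0,
    beta_high: float = 0.9,
    beta_low: float = 0.1,
) -> ReferencePanel:
    """Build a separable reference panel with two cancer expression variants.

    Each of the ``k`` methylation archetypes owns a block of discriminative
    probes (beta ~ ``beta_high`` in its own class, ~ ``beta_low`` elsewhere);
    remaining probes share a class-independent background.  Expression
    profiles are nonnegative with class-specific structure; the gene of
    interest (``variant_gene``) is expressed only in cancer cells and its
    level differs ``variant_fold``-fold between the two cancer variants.
    """
    if not isinstance(k, (int, np.integer)) or k < 2:
        raise ValueError(f"k must be an integer >= 2, got {k!r}")
    if n_probes < 10 * k:
        raise ValueError(f"n_probes must be >= 10*k = {10 * k}, got {n_probes}")
    _check_positive("variant_fold", variant_fold)
    if variant_fold <= 1:
        raise ValueError(f"variant_fold must exceed 1, got {variant_fold}")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")

    rng = np.random.default_rng(seed)
    labels = _NONCANCER_NAMES[: k - 1] + [CANCER]
    if k - 1 > len(_NONCANCER_NAMES):
        labels = [f"stroma{i}" for i in range(k - 1)] + [CANCER]

    probes = [f"cg{i:07d}" for i in range(n_probes)]
    n_own = n_probes // (2 * k)  # discriminative block per class
    M = np.empty((n_probes, k))
    n_disc = n_own * k
    # shared background for non-discriminative probes
    background = rng.beta(2.0, 2.0, size=n_probes - n_disc)
    M[n_disc:, :] = background[:, None]
    jitter = lambda size: rng.uniform(-0.03, 0.03, size=size)  # noqa: E731
    for c in range(k):
        block = slice(c * n_own, (c + 1) * n_own)
        M[block, :] = np.clip(beta_low + jitter((n_own, k)), 0.0, 1.0)
        M[block, c] = np.clip(beta_high + jitter(n_own), 0.0, 1.0)
    meth = pd.DataFrame(M, index=probes, columns=labels)

    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    variant_gene = genes[0]
    expr_cols = labels[:-1] + [VARIANT_HI, VARIANT_LO]
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n_genes)
    E = base[:, None] * rng.lognormal(mean=0.0, sigma=0.7, size=(n_genes, len(expr_cols)))
    # the two cancer variants are identical except for the gene of interest
    hi_idx = expr_cols.index(VARIANT_HI)
    lo_idx = expr_cols.index(VARIANT_LO)
    E[:, lo_idx] = E[:, hi_idx]
    goi_lo = 10.0
    E[0, :] = 0.0  # gene of interest is cancer-cell specific
    E[0, lo_idx] = goi_lo
    E[0, hi_idx] = goi_lo * variant_fold
    expr = pd.DataFrame(E, index=genes, columns=expr_cols)

    return ReferencePanel(
        class_labels=labels,
        meth_profiles=meth,
        expr_profiles=expr,
        variant_gene=variant_gene,
        variant_fold=float(variant_fold),
    )


def _beta_noise(rng: np.random.Generator, means: np.ndarray, precision: float) -> np.ndarray:
    """Mean-preserving Beta resampling of beta values with concentration ``precision``."""
    m = np.clip(means, 1e-6, 1.0 - 1e-6)
    return rng.beta(m * precision, (1.0 - m) * precision)


def simulate_mixtures(
    panel: ReferencePanel,
    n_per_variant: int,
    alpha: np.ndarray | list[float] | None = None,
    noise_precision: float | None = 100.0,
    seed: int = 0,
    expression_noise: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame, MixtureTruth]:
    """Simulate paired bulk methylation and expression mixtures.

    Each sample draws proportions p ~ Dirichlet(alpha) over the k cell
    types; its methylation column is ``M_noisy @ p`` (per-probe Beta noise
    with concentration ``noise_precision``, or noiseless when ``None``) and
    its expression column is ``E_variant @ p`` with the *same* p and the
    sample's assigned cancer variant.  ``n_per_variant`` samples are drawn
    per variant (one block per variant when the panel carries two).
    """
    if n_per_variant < 1:
        raise ValueError("n_per_variant must be >= 1")
    k = panel.k
    if alpha is None:
        alpha = np.ones(k)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (k,) or np.any(alpha <= 0) or not np.isfinite(alpha).all():
        raise ValueError(f"alpha must be a length-{k} vector of positive concentrations")
    if noise_precision is not None:
        _check_positive("noise_precision", noise_precision)
    if expression_noise not in ("none", "poisson"):
        raise ValueError("expression_noise must be 'none' or 'poisson'")

    rng = np.random.default_rng(seed)
    variants = [VARIANT_HI, VARIANT_LO] if panel.has_variants else [CANCER]
    n_samples = n_per_variant * len(variants)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    variant_of = pd.Series(
        [variants[i // n_per_variant] for i in range(n_samples)], index=sample_ids
    )

    P = rng.dirichlet(alpha, size=n_samples).T  # k x n
    M_ref = panel.meth_profiles.to_numpy()
    meth = np.empty((M_ref.shape[0], n_samples))
    for j in range(n_samples):
        M_j = M_ref if noise_precision is None else _beta_noise(rng, M_ref, noise_precision)
        meth[:, j] = M_j @ P[:, j]

    expr_by_variant = {v: panel.expr_for_variant(v).to_numpy() for v in set(variant_of)}
    if not panel.has_variants:
        expr_by_variant = {CANCER: panel.expr_profiles[panel.class_labels].to_numpy()}
    expr = np.empty((panel.expr_profiles.shape[0], n_samples))
    for j, sid in enumerate(sample_ids):
        expr[:, j] = expr_by_variant[variant_of[sid]] @ P[:, j]
    if expression_noise == "poisson":
        expr = rng.poisson(expr).astype(float)

    meth_df = pd.DataFrame(meth, index=panel.meth_profiles.index, columns=sample_ids)
    expr_df = pd.DataFrame(expr, index=panel.expr_profiles.index, columns=sample_ids)
    truth = MixtureTruth(
        P_true=pd.DataFrame(P, index=panel.class_labels, columns=sample_ids),
        assigned_variant=variant_of,
        noise_precision=noise_precision,
        dirichlet_alpha=alpha,
        seed=int(seed),
        expression_noise=expression_noise,
    )
    return meth_df, expr_df, truth


def simulate_purity_confounding(
    seed: int = 0,
    n_samples: int = 150,
    alpha: tuple[float, ...] = (2.0, 2.0, 1.0),
    noise_sd: float = 0.1,
    n_null_genes: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, str, str]:
    """A composition-confounding scenario for network inference.

    Two genes are each expressed in a different cell type — gene ``A``
    scales with the cancer proportion, gene ``B`` with the stromal
    proportion — so their bulk values correlate strongly across samples
    even though no regulatory link exists; additional genes are pure
    lognormal noise.  Returns (expression, proportions, gene_a, gene_b).
    Used to demonstrate that proportion covariate nodes suppress the
    spurious gene-gene edge.
    """
    rng = np.random.default_rng(seed)
    Pm = rng.dirichlet(alpha, size=n_samples).T
    samples = [f"s{i:03d}" for i in range(n_samples)]
    P = pd.DataFrame(Pm, index=["cancer", "stroma", "immune"][: len(alpha)], columns=samples)
    rows = {
        "A": 200.0 * Pm[0] * rng.lognormal(0.0, noise_sd, n_samples),
        "B": 150.0 * Pm[1] * rng.lognormal(0.0, noise_sd, n_samples),
    }
    for j in range(n_null_genes):
        rows[f"N{j}"] = rng.lognormal(3.0, 0.5, n_samples)
    G = pd.DataFrame(rows, index=samples).T
    return G, P, "A", "B"


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(truth: MixtureTruth, directory: str | Path) -> None:
    """Write ground truth as a samples x cell-types TSV plus a JSON metadata record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.P_true.T.to_csv(directory / "true_proportions.tsv", sep="\t", index_label="sample")
    truth.assigned_variant.rename("variant").to_csv(
        directory / "true_variants.tsv", sep="\t", index_label="sample"
    )
    meta = {
        "noise_precision": truth.noise_precision,
        "dirichlet_alpha": list(map(float, truth.dirichlet_alpha)),
        "seed": truth.seed,
        "expression_noise": truth.expression_noise,
    }
    (directory / "truth_meta.json").write_text(json.dumps(meta, indent=2))
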