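"""Among-strain variation in mutation spectra and life-history correlates.

Pairwise G-tests on raw class counts quantify how often two strains'
spectra differ; principal component analysis of the standardized class
frequencies (columns zero-centred and scaled to unit variance, components
from the SVD of the scaled matrix) summarizes the major axes of spectrum
variation; Spearman correlations and one-way ANOVA relate the spectrum and
its principal components to strain breeding traits.

Pairwise tests use raw counts rather than standardized frequencies — a
count-based likelihood-ratio test needs integer observations — and are
reported without multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .neutrality import g_test

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    loadings: pd.DataFrame        # classes x components
    scores: pd.DataFrame          # strains x components
    variance_fractions: np.ndarray
    dropped_columns: list[str]


# ---------------------------------------------------------------------------
# pairwise spectrum heterogeneity
# ---------------------------------------------------------------------------

def pairwise_spectrum_gtests(counts: pd.DataFrame, alpha: float = 0.05
                             ) -> tuple[pd.DataFrame, float]:
    """G-test of spectrum independence for every unordered strain pair.

    ``counts`` is a strains x classes table of raw integer counts. Each
    pair is tested as a 2 x c contingency table (df = c-1, uncorrected p).
    Returns the per-pair table and the fraction of pairs significant at
    ``alpha``.
    """
    strains = list(counts.index)
    rows = []
    for a, b in combinations(strains, 2):
        g, df, p = g_test(counts.loc[[a, b]].to_numpy())
        rows.append({"strain_a": a, "strain_b": b, "G": g, "df": df, "p": p})
    pairs = pd.DataFrame(rows)
    frac = float((pairs["p"] < alpha).mean()) if len(pairs) else float("nan")
    logger.info("%d pairs, %.1f%% significantly distinct at alpha=%g",
                len(pairs), 100 * frac, alpha)
    return pairs, frac


def n_strain_pairs(n_strains: int) -> int:
    """Number of unordered strain pairs, C(n, 2)."""
    return n_strains * (n_strains - 1) // 2


# ---------------------------------------------------------------------------
# PCA of spectra
# ---------------------------------------------------------------------------

def pca_spectra(frequencies: pd.DataFrame) -> PCAResult:
    """PCA of per-strain class frequencies.

    Columns are zero-centred and scaled to unit (sample) variance;
    zero-variance columns are dropped with a warning since scaling is
    undefined for them. Components come from the singular value
    decomposition of the scaled matrix; variance-explained fractions sum to
    one, and each component's sign is fixed so that its largest-magnitude
    loading is positive.
    """
    X = frequencies.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(frequencies.columns, sd) if s == 0]
    if dropped:
        logger.warning("dropping zero-variance columns: %s", dropped)
    keep = sd > 0
    cols = [c for c, k in zip(frequencies.columns, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|loading| of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=cols, columns=comp_names),
        scores=pd.DataFrame(scores, index=frequencies.index,
                            columns=comp_names),
        variance_fractions=frac, dropped_columns=dropped)


# ---------------------------------------------------------------------------
# trait statistics
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]
                  ) -> tuple[float, int, int, float]:
    """One-way ANOVA across groups: (F, df_between, df_within, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    all_vals = np.concatenate(arrays)
    if np.allclose(all_vals, all_vals[0]):
        raise ValueError("total variance is zero; F undefined")
    df1 = len(arrays) - 1
    df2 = len(all_vals) - len(arrays)
    res = stats.f_oneway(*arrays)
    return float(res.statistic), df1, df2, float(res.pvalue)


def anova_by_strain(traits: pd.DataFrame, trait: str
                    ) -> tuple[float, int, int, float]:
    """Among-strain ANOVA for one trait from a long-format trait table."""
    sub = traits[traits["trait"] == trait]
    groups = [g["value"].to_numpy() for _, g in sub.groupby("strain")]
    return one_way_anova(groups)


def trait_spectrum_report(frequencies: pd.DataFrame, traits: pd.DataFrame,
                          pca: PCAResult | None = None) -> pd.DataFrame:
    """Spearman correlations of PC1 and each class frequency with each trait.

    Trait values are per-strain replicate means; strains present in only one
    of the two inputs are dropped. A trait constant across strains yields an
    undefined correlation, reported as missing.
    """
    if pca is None:
        pca = pca_spectra(frequencies)
    trait_means = (traits.groupby(["strain", "trait"])["value"].mean()
                   .unstack("trait"))
    strains = [s for s in frequencies.index if s in trait_means.index]
    if len(strains) < 3:
        raise ValueError("need >= 3 strains shared between spectra and "
                         "traits")
    predictors = {"PC1": pca.scores.loc[strains, "PC1"].to_numpy()}
    for cls in frequencies.columns:
        predictors[f"% {cls}"] = frequencies.loc[strains, cls].to_numpy()
    rows = []
    for trait in trait_means.columns:
        t = trait_means.loc[strains, trait].to_numpy()
        for name, v in predictors.items():
            if np.allclose(t, t[0]) or np.allclose(v, v[0]):
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(v, t)
            rows.append({"trait": trait, "predictor": name,
                         "rho": rho, "p": p})
    return pd.DataFrame(rows)
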