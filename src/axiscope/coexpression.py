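"""Stochastic-independence analysis of transcription-factor coexpression.

Single-cell libraries detect a gene in only a fraction of the cells that
transcribe it.  If TF genes P and Q are expressed stochastically and
independently, and are detected in fractions ``p`` and ``q`` of the cell
population, the fraction of cells with both detected is predicted to be the
product ``p * q``.  This module turns a count matrix into binary detection
calls, tabulates the disjoint Venn regions for gene pairs and trios,
compares observed coexpression fractions with the ``p * q`` prediction via a
least-squares regression line constrained through the origin, and
diagnoses the systematic excess the prediction misses: read depth varies
widely between cells, detection of *every* gene is more likely in deeply
read cells, so pooled coexpression exceeds the product of pooled marginals
even under true independence.  Stratifying cells by depth removes the
shared covariate — within strata the regression slope returns to ~1 while
the pooled slope stays above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .types import CountMatrix

#: Gene sets of the three coexpression panels analysed on the XN1 line:
#: anteroposterior TFs, dorsoventral TFs (a reconstruction of the panel from
#: the genes named for that line; configurable), and the mixed A/P-D/V trio.
AP_TRIO: tuple[str, ...] = ("Otx2", "En2", "Hoxa5")
DV_TRIO: tuple[str, ...] = ("Pax6", "Irx3", "Nkx2-2")
MIXED_TRIO: tuple[str, ...] = ("En2", "Hoxa5", "Pax6")


def default_pair_set(
    panels: Sequence[Sequence[str]] = (AP_TRIO, DV_TRIO, MIXED_TRIO),
) -> list[tuple[str, str]]:
    """All within-panel gene pairs over the three panels, de-duplicated."""
    pairs: list[tuple[str, str]] = []
    seen = set()
    for panel in panels:
        for a, b in combinations(panel, 2):
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                pairs.append((a, b))
    return pairs


@dataclass(frozen=True)
class DetectionProfile:
    """Per-gene detection fractions (the marginal p's) over n_cells."""

    fractions: pd.Series
    n_cells: int

    def __getitem__(self, gene: str) -> float:
        if gene not in self.fractions.index:
            raise KeyError(f"gene {gene!r} not in detection profile")
        return float(self.fractions[gene])


@dataclass(frozen=True)
class VennPartition:
    """Disjoint-region cell fractions for a pair or trio of genes.

    Regions are keyed by the tuple of detected genes (in panel order); the
    empty tuple is the none-detected region.  Fractions are exact ratios of
    cell counts and sum to 1.
    """

    genes: tuple[str, ...]
    fractions: dict[tuple[str, ...], float]
    n_cells: int

    def union_fraction(self, genes: Sequence[str] | None = None) -> float:
        """Fraction of cells with at least one of ``genes`` detected."""
        want = set(self.genes if genes is None else genes)
        return sum(f for region, f in self.fractions.items() if want & set(region))

    def detected_fraction(self, genes: Sequence[str]) -> float:
        """Fraction of cells with all of ``genes`` detected (marginal/joint)."""
        want = set(genes)
        return sum(f for region, f in self.fractions.items() if want <= set(region))


@dataclass(frozen=True)
class IndependenceFit:
    """Observed vs predicted coexpression with a through-origin line."""

    pairs: list[tuple[str, ...]]
    observed: np.ndarray
    predicted: np.ndarray
    slope: float
    r_squared: float
    r2_convention: str = "uncentered"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": ["&".join(p) for p in self.pairs],
                "observed": self.observed,
                "predicted": self.predicted,
            }
        )


# --- detection -------------------------------------------------------------


def detect(counts: CountMatrix, min_count: int = 1) -> pd.DataFrame:
    """Binary detection calls: True where count >= min_count."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return pd.DataFrame(
        counts.X >= min_count, index=pd.Index(counts.genes, name="gene"),
        columns=counts.cells,
    )


def detection_fractions(binary: pd.DataFrame) -> DetectionProfile:
    """Per-gene fraction of cells detected."""
    if binary.shape[1] == 0:
        raise ValueError("cannot compute detection fractions over zero cells")
    return DetectionProfile(fractions=binary.mean(axis=1), n_cells=binary.shape[1])


def venn_partition(binary: pd.DataFrame, genes: Sequence[str]) -> VennPartition:
    """Disjoint detection-pattern fractions for 2 or 3 named genes."""
    genes = tuple(genes)
    if not 2 <= len(genes) <= 3:
        raise ValueError("venn_partition takes 2 or 3 genes")
    missing = [g for g in genes if g not in binary.index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    B = binary.loc[list(genes)].to_numpy()
    n = B.shape[1]
    # encode each cell's detection pattern as a bitmask over the panel
    codes = np.zeros(n, dtype=int)
    for i in range(len(genes)):
        codes |= B[i].astype(int) << i
    counts = np.bincount(codes, minlength=2 ** len(genes))
    fractions = {
        tuple(g for i, g in enumerate(genes) if code >> i & 1): int(c) / n
        for code, c in enumerate(counts)
    }
    return VennPartition(genes=genes, fractions=fractions, n_cells=n)


def predicted_coexpression(profile: DetectionProfile, genes: Sequence[str]) -> float:
    """Independence prediction: the product of marginal detection fractions."""
    out = 1.0
    for g in genes:
        out *= profile[g]
    return out


def observed_coexpression(binary: pd.DataFrame, genes: Sequence[str]) -> float:
    """Fraction of cells in which every named gene is detected."""
    missing = [g for g in genes if g not in binary.index]
    if missing:
        raise KeyError(f"gene(s) not in matrix: {missing}")
    return float(binary.loc[list(genes)].all(axis=0).mean())


# --- through-origin regression ---------------------------------------------


def fit_through_origin(
    observed: Sequence[float],
    predicted: Sequence[float],
    pairs: Sequence[tuple[str, ...]] | None = None,
    r2: str = "uncentered",
) -> IndependenceFit:
    """Least-squares line y = b*x constrained through the origin.

    With x the predicted and y the observed coexpression fractions,
    ``slope = sum(x*y) / sum(x^2)``.  The fit quality is reported as the
    uncentered R^2 = 1 - SS_res / sum(y^2) by default (the natural
    convention for a no-intercept model); ``r2="corr"`` reports the squared
    Pearson correlation instead.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    if len(x) < 2:
        raise ValueError("need at least two pairs to fit")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("slope undefined: predicted values are all zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    if r2 == "uncentered":
        syy = float(y @ y)
        r_squared = 1.0 - float(resid @ resid) / syy if syy > 0 else float("nan")
    elif r2 == "corr":
        r_squared = float(np.corrcoef(x, y)[0, 1]) ** 2
    else:
        raise ValueError(f"unknown R^2 convention {r2!r}")
    if pairs is None:
        pairs = [(f"pair{i}",) for i in range(len(x))]
    return IndependenceFit(
        pairs=list(pairs), observed=y, predicted=x, slope=slope,
        r_squared=r_squared, r2_convention=r2,
    )


def _pairwise_obs_pred(
    binary: pd.DataFrame, pairs: Sequence[tuple[str, ...]]
) -> tuple[np.ndarray, np.ndarray]:
    """Observed joint and product-of-marginals fractions for each gene set."""
    genes = sorted({g for p in pairs for g in p})
    B = binary.loc[genes].to_numpy(dtype=float)
    n = B.shape[1]
    marg = B.mean(axis=1)
    joint2 = (B @ B.T) / n  # pairwise joint detection fractions
    row = {g: i for i, g in enumerate(genes)}
    obs = np.empty(len(pairs))
    pred = np.empty(len(pairs))
    for k, p in enumerate(pairs):
        idx = [row[g] for g in p]
        pred[k] = marg[idx].prod()
        if len(idx) == 2:
            obs[k] = joint2[idx[0], idx[1]]
        else:
            obs[k] = B[idx].prod(axis=0).mean()
    return obs, pred


def independence_fit(
    counts: CountMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
    min_count: int = 1,
    r2: str = "uncentered",
) -> IndependenceFit:
    """Observed-vs-predicted coexpression fit over a pair set.

    Default pair set: all pairs among the matrix's genes.
    """
    binary = detect(counts, min_count=min_count)
    if binary.shape[1] == 0:
        raise ValueError("cannot fit over zero cells")
    if pairs is None:
        pairs = list(combinations(counts.genes, 2))
    obs, pred = _pairwise_obs_pred(binary, pairs)
    return fit_through_origin(obs, pred, pairs=pairs, r2=r2)


# --- depth-inflation diagnostic --------------------------------------------


@dataclass(frozen=True)
class DepthInflationReport:
    """Depth-stratified coexpression diagnostic.

    ``per_stratum`` holds, for each depth stratum (ordered shallow to deep),
    the per-pair observed coexpression and the within-stratum
    observed-vs-predicted slope.  ``monotone_pairs`` marks pairs whose
    observed coexpression is nondecreasing from the shallowest to the
    deepest stratum.
    """

    pairs: list[tuple[str, str]]
    n_strata: int
    stratum_sizes: list[int]
    observed_by_stratum: pd.DataFrame  # strata x pairs
    stratum_slopes: list[float]
    pooled_slope: float
    monotone_pairs: pd.Series = field(repr=False)

    @property
    def monotone_fraction(self) -> float:
        return float(self.monotone_pairs.mean())


def depth_inflation_diagnostic(
    counts: CountMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_strata: int = 4,
    min_count: int = 1,
) -> DepthInflationReport:
    """Split cells into depth quantile strata and re-test independence within.

    Strata are equal-size rank bins of per-cell depth (recorded multiplier
    when available, else total counts).  Under independent on/off expression
    the within-stratum slopes sit near 1 regardless of the depth law, while
    the pooled slope exceeds 1 whenever depth varies — the signature that
    excess coexpression is a read-depth artifact rather than co-regulation.
    """
    if n_strata < 2:
        raise ValueError("need at least two depth strata")
    if counts.n_cells < n_strata:
        raise ValueError(
            f"{counts.n_cells} cells cannot fill {n_strata} depth strata"
        )
    if pairs is None:
        pairs = list(combinations(counts.genes, 2))
    pairs = [tuple(p) for p in pairs]

    order = np.argsort(counts.depth, kind="stable")
    strata = np.array_split(order, n_strata)

    binary_all = detect(counts, min_count=min_count)
    pooled_obs, pooled_pred = _pairwise_obs_pred(binary_all, pairs)
    pooled = fit_through_origin(pooled_obs, pooled_pred, pairs=pairs)

    obs_rows, slopes, sizes = [], [], []
    for idx in strata:
        obs, pred = _pairwise_obs_pred(binary_all.iloc[:, idx], pairs)
        slopes.append(fit_through_origin(obs, pred, pairs=pairs).slope)
        obs_rows.append(obs)
        sizes.append(len(idx))

    labels = ["&".join(p) for p in pairs]
    obs_df = pd.DataFrame(
        obs_rows, index=[f"stratum{i + 1}" for i in range(n_strata)], columns=labels
    )
    monotone = pd.Series(
        (np.diff(obs_df.to_numpy(), axis=0) >= 0).all(axis=0), index=labels
    )
    return DepthInflationReport(
        pairs=list(pairs),
        n_strata=n_strata,
        stratum_sizes=sizes,
        observed_by_stratum=obs_df,
        stratum_slopes=slopes,
        pooled_slope=pooled.slope,
        monotone_pairs=monotone,
    )
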