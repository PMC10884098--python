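"""Synthetic data generators for the three analysis stages.

Three generators emulate the statistical structure the analyses assume:

* ``simulate_sc_counts`` — single-cell counts under stochastic on/off gene
  expression.  Each cell expresses gene *g* with probability ``p_g``
  independently across genes and cells; an expressing cell yields a
  Poisson-distributed transcript count with mean ``d_c * m_g`` where ``d_c``
  is the cell's capture-depth multiplier and ``m_g`` the gene's mean capture
  at unit depth.  Heterogeneous depth (default log-normal) makes detection
  of *every* gene more likely in deeply read cells, which inflates observed
  coexpression above the product of marginal detection fractions — the
  mechanism the coexpression module diagnoses.
* ``simulate_tracks`` — planar cell trajectories sampled at fixed frame
  intervals under configurable group velocity fields with positional noise,
  emulating time-lapse epiblast recordings (+y is posterior).
* ``simulate_bulk_profiles`` — replicated bulk intensity tables from an
  off/low/high tier code per sample and gene, emulating microarray profiles
  of the NSC lines.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix

Velocity = tuple[float, float] | Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class DepthDist:
    """Per-cell depth multiplier distribution.

    ``lognormal`` draws exp(sigma*Z) with Z standard normal (median depth 1);
    ``constant`` fixes every cell's depth at ``value``.
    """

    family: str = "lognormal"
    sigma: float = 0.8
    value: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "constant":
            if self.value <= 0:
                raise ValueError("constant depth must be positive")
            return np.full(n, float(self.value))
        if self.family == "lognormal":
            if self.sigma < 0:
                raise ValueError("lognormal sigma must be >= 0")
            return np.exp(rng.normal(0.0, self.sigma, size=n))
        raise ValueError(f"unknown depth distribution family {self.family!r}")

    def mean_detection(self, m_g: float, n_grid: int = 20001) -> float:
        """E_d[1 - exp(-d * m_g)] by numerical integration over the depth law."""
        if self.family == "constant":
            return 1.0 - np.exp(-self.value * m_g)
        from scipy import integrate, stats

        if self.sigma == 0:
            return 1.0 - np.exp(-m_g)
        law = stats.lognorm(s=self.sigma)
        lo, hi = law.ppf(1e-10), law.ppf(1 - 1e-10)
        d = np.linspace(lo, hi, n_grid)
        return float(integrate.trapezoid((1.0 - np.exp(-d * m_g)) * law.pdf(d), d))


@dataclass(frozen=True)
class SCSimParams:
    """Parameters of the stochastic on/off single-cell count model."""

    n_cells: int
    genes: Sequence[str]
    expr_prob: Mapping[str, float]
    mean_capture: Mapping[str, float]
    depth: DepthDist = field(default_factory=DepthDist)
    line: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for g in self.genes:
            p = self.expr_prob[g]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"expression probability of {g} must be in [0, 1], got {p}")
            if self.mean_capture[g] <= 0:
                raise ValueError(f"mean capture of {g} must be positive")


#: G2-M phase marker genes whose capture is scaled in cycling cells when the
#: optional cell-cycle label is simulated.
G2M_MARKERS: tuple[str, ...] = ("Hmgb2", "Mki67", "Top2a")


def simulate_sc_counts(
    params: SCSimParams,
    cycle_fraction: float = 0.0,
    cycle_depth_factor: float = 3.0,
) -> CountMatrix:
    """Draw a genes x cells count matrix under the on/off Poisson model.

    Optionally labels a ``cycle_fraction`` of cells as G2-M and scales the
    capture mean of the G2-M marker genes by ``cycle_depth_factor`` in those
    cells; no cell-cycle inference is performed anywhere in the package.
    """
    rng = np.random.default_rng(params.seed)
    genes = list(params.genes)
    n, G = params.n_cells, len(genes)

    depth = params.depth.sample(n, rng)
    p = np.array([params.expr_prob[g] for g in genes])
    m = np.array([params.mean_capture[g] for g in genes])

    on = rng.random((G, n)) < p[:, None]
    lam = m[:, None] * depth[None, :]
    if cycle_fraction:
        phase = rng.random(n) < cycle_fraction
        idx = [i for i, g in enumerate(genes) if g in G2M_MARKERS]
        if idx:
            lam[np.ix_(idx, phase)] *= cycle_depth_factor
    else:
        phase = None
    counts = np.where(on, rng.poisson(lam), 0).astype(np.int64)

    cells = [f"cell{i:05d}" for i in range(n)]
    meta = pd.DataFrame({"depth_multiplier": depth}, index=cells)
    if phase is not None:
        meta["phase"] = np.where(phase, "G2M", "other")
    return CountMatrix(
        genes=genes, cells=cells, X=counts, cell_meta=meta, line=params.line
    )


def expected_detection_fraction(params: SCSimParams, gene: str) -> float:
    """Closed-form detection fraction p_g * E_d[1 - exp(-d * m_g)]."""
    return params.expr_prob[gene] * params.depth.mean_detection(params.mean_capture[gene])


def panel_params(
    n_cells: int,
    n_genes: int = 20,
    depth: DepthDist | None = None,
    p_range: tuple[float, float] = (0.05, 0.5),
    m_range: tuple[float, float] = (1.0, 3.0),
    seed: int = 0,
) -> SCSimParams:
    """Reference simulation setup for independence calibration studies.

    A panel of TF-like genes with expression probabilities spread over
    ``p_range`` and unit-depth capture means over ``m_range`` (drawn from a
    seed-derived stream so the panel is reproducible but not degenerate).
    Defaults model sparsely detected TFs in a variably sequenced library.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E37]))
    genes = [f"tf{i:02d}" for i in range(n_genes)]
    p = rng.uniform(*p_range, n_genes)
    m = rng.uniform(*m_range, n_genes)
    return SCSimParams(
        n_cells=n_cells,
        genes=genes,
        expr_prob=dict(zip(genes, p)),
        mean_capture=dict(zip(genes, m)),
        depth=depth if depth is not None else DepthDist(),
        seed=seed,
    )


# --- trajectories ----------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One labeled cell population: a velocity field and a seeding region."""

    n_cells: int
    velocity: Velocity
    start_box: tuple[float, float, float, float] = (0.0, 0.0, 500.0, 500.0)

    def velocity_at(self, pos: np.ndarray) -> np.ndarray:
        """Velocity (µm/h) at positions ``pos`` of shape (n, 2)."""
        if callable(self.velocity):
            return np.asarray(self.velocity(pos), dtype=float)
        return np.broadcast_to(np.asarray(self.velocity, float), pos.shape).copy()


@dataclass(frozen=True)
class FieldSpec:
    """Track-simulation setup: groups, frame grid and positional noise."""

    groups: Mapping[str, GroupSpec]
    n_frames: int = 12
    frame_interval_min: float = 10.0
    noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("need at least three frames to estimate velocities")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        if self.noise_sd_um < 0:
            raise ValueError("positional noise sd must be >= 0")
        if not self.groups:
            raise ValueError("at least one cell group is required")


def simulate_tracks(spec: FieldSpec) -> pd.DataFrame:
    """Simulate labeled-cell trajectories on a uniform frame grid.

    Cells start uniformly in their group's seeding box; each frame's
    displacement is ``velocity(position) * frame_interval`` plus isotropic
    Gaussian positional noise.  Returns a table with columns
    ``cell_id, group, frame, t_min, x_um, y_um``.
    """
    rng = np.random.default_rng(spec.seed)
    dt_h = spec.frame_interval_min / 60.0
    rows = []
    cell_no = 0
    for name, grp in spec.groups.items():
        x0, y0, x1, y1 = grp.start_box
        pos = np.column_stack(
            [rng.uniform(x0, x1, grp.n_cells), rng.uniform(y0, y1, grp.n_cells)]
        )
        ids = [f"{name}_{cell_no + i:05d}" for i in range(grp.n_cells)]
        cell_no += grp.n_cells
        for frame in range(spec.n_frames):
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": ids,
                        "group": name,
                        "frame": frame,
                        "t_min": frame * spec.frame_interval_min,
                        "x_um": pos[:, 0],
                        "y_um": pos[:, 1],
                    }
                )
            )
            step = grp.velocity_at(pos) * dt_h
            if spec.noise_sd_um:
                step = step + rng.normal(0.0, spec.noise_sd_um, size=pos.shape)
            pos = pos + step
    return pd.concat(rows, ignore_index=True).sort_values(
        ["cell_id", "frame"], kind="stable", ignore_index=True
    )


# --- bulk profiles ----------------------------------------------------------


@dataclass(frozen=True)
class BulkSimParams:
    """Bulk-profile simulation from an off/low/high tier code.

    ``code`` maps sample -> gene -> tier.  Intensities are the tier mean
    times a multiplicative log-normal noise factor with unit mean; two
    biological replicates per sample by default.
    """

    code: Mapping[str, Mapping[str, str]]
    tier_means: Mapping[str, float] = field(
        default_factory=lambda: {"off": 0.0, "low": 0.25, "high": 1.0}
    )
    n_replicates: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for sample, tiers in self.code.items():
            for gene, tier in tiers.items():
                if tier not in self.tier_means:
                    raise ValueError(f"unknown tier {tier!r} for {sample}/{gene}")


def simulate_bulk_profiles(params: BulkSimParams) -> pd.DataFrame:
    """Genes x sample-replicate intensity table realizing a tier code.

    Columns are named ``<sample>_<replicate>``; replicate indices start at 1.
    With ``noise_sd == 0`` the table holds the tier means exactly.
    """
    rng = np.random.default_rng(params.seed)
    genes = sorted({g for tiers in params.code.values() for g in tiers})
    cols = {}
    for sample, tiers in params.code.items():
        means = np.array([params.tier_means[tiers.get(g, "off")] for g in genes])
        for rep in range(1, params.n_replicates + 1):
            if params.noise_sd:
                factor = np.exp(
                    rng.normal(0.0, params.noise_sd, size=len(genes))
                    - params.noise_sd**2 / 2.0
                )
            else:
                factor = 1.0
            cols[f"{sample}_{rep}"] = means * factor
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
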