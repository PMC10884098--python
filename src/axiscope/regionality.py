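"""Anteroposterior regional-coverage calls from bulk expression profiles.

The pipeline is: per-gene max-normalization of replicate-averaged
intensities, binning of normalized values into off/low/high tiers, and a
rule-based classifier that converts a sample's tier profile into an interval
on the A/P axis using the Hox class code.  High-tier evidence defines the
*core* interval; low-tier evidence may only widen it into the *extended*
interval.  A companion check assesses whether a profile carries a coherent
dorsoventral identity.

Classifier rules
----------------
Every marker carries an (anterior limit, posterior extent) pair of axis
positions: brain markers resolve by anteriority (Foxg1 supports a
forebrain start, Otx2 a midbrain start, En2 a hindbrain start; their
extents end at the posterior MB for Otx2 and the anterior HB for En2),
and Hox genes carry their class boundary domain's posterior half unless a
stated anterior-boundary staggering refines it — Hoxa5 reaches only the
anterior CSC (its boundary lies anterior to Hoxb5's), Hoxa6/a7 and
Hoxb7-b9 only the anterior TSC (Hoxa9/a10 mark the posterior TSC), Hoxc9
stays within the TSC while Hoxc10/c11 extend coverage to the lumbar cord.
A sample's interval is the minimum anterior limit and maximum posterior
extent over its expressed markers, which reproduces the published
inferences (e.g. Hoxa5 without Hoxb5 stops in the anterior CSC; a
brain-marker-free HB+CSC profile starts in the posterior HB) and makes
both limits monotone in every gene's tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import DV_CODE, TIERS, AxisPosition, HoxCode

logger = logging.getLogger(__name__)

_TIER_RANK = {t: i for i, t in enumerate(TIERS)}


@dataclass(frozen=True)
class RegionCall:
    """A/P coverage interval called for one sample."""

    sample: str
    core: tuple[AxisPosition, AxisPosition] | None
    extended: tuple[AxisPosition, AxisPosition] | None
    evidence: dict[str, str] = field(default_factory=dict)

    @property
    def undetermined(self) -> bool:
        return self.extended is None

    def __str__(self) -> str:
        if self.undetermined:
            return f"{self.sample}: undetermined"
        parts = [f"{self.sample}: core {self.core[0]} - {self.core[1]}"]
        if self.extended != self.core:
            parts.append(f"extended {self.extended[0]} - {self.extended[1]}")
        return "; ".join(parts)


@dataclass(frozen=True)
class DVCall:
    """Dorsoventral identity call: a class name or 'ambiguous' with reasons."""

    sample: str
    call: str
    complete_classes: tuple[str, ...]
    violations: tuple[str, ...]


# --- normalization and tiers ---------------------------------------------


def average_replicates(table: pd.DataFrame, sep: str = "_") -> pd.DataFrame:
    """Average replicate columns named ``<sample><sep><index>``.

    Columns without a trailing ``<sep><integer>`` are treated as single
    replicates of themselves.
    """

    def sample_of(col: str) -> str:
        stem, _, tail = col.rpartition(sep)
        return stem if stem and tail.isdigit() else col

    groups = [sample_of(c) for c in table.columns]
    out = table.T.groupby(groups, sort=False).mean().T
    return out


def max_normalize(
    table: pd.DataFrame,
    reference_samples: list[str] | None = None,
    replicate_sep: str | None = "_",
) -> tuple[pd.DataFrame, list[str]]:
    """Scale each gene so its maximum over the reference samples is 1.0.

    Parameters
    ----------
    table
        Genes x samples (or genes x sample-replicate) non-negative
        intensities.  Replicate columns are averaged first when
        ``replicate_sep`` is given.
    reference_samples
        Samples over which the per-gene maximum is taken.  Default: all
        samples.  Restricting the reference to embryo-portion samples lets
        cell-line values exceed 1.
    Returns
    -------
    (normalized, flagged)
        The normalized table and the genes whose reference maximum was 0
        (flagged not-expressed; their values are left untouched).
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("expression intensities must be non-negative")
    if replicate_sep is not None:
        table = average_replicates(table, sep=replicate_sep)
    ref = table if reference_samples is None else table[list(reference_samples)]
    gene_max = ref.max(axis=1)
    flagged = list(table.index[gene_max == 0])
    if flagged:
        logger.info("%d gene(s) with zero reference maximum flagged not-expressed", len(flagged))
    scale = gene_max.replace(0, 1.0)
    return table.div(scale, axis=0), flagged


def tier_binning(value: float, thresholds: tuple[float, float] = (0.1, 0.5)) -> str:
    """Bin a normalized value into off/low/high.

    Boundaries are inclusive upward: ``value == thresholds[0]`` is low and
    ``value == thresholds[1]`` is high.
    """
    lo, hi = thresholds
    if not 0 <= lo < hi:
        raise ValueError("thresholds must satisfy 0 <= low < high")
    if value < 0 or not np.isfinite(value):
        raise ValueError(f"normalized expression must be finite and >= 0, got {value}")
    if value < lo:
        return "off"
    if value < hi:
        return "low"
    return "high"


def tier_table(
    normalized: pd.DataFrame, thresholds: tuple[float, float] = (0.1, 0.5)
) -> pd.DataFrame:
    """Apply :func:`tier_binning` elementwise to a genes x samples table."""
    return normalized.map(lambda v: tier_binning(v, thresholds))


# --- A/P classification ----------------------------------------------------


def _expressed(tiers: dict[str, str], min_tier: str) -> set[str]:
    cut = _TIER_RANK[min_tier]
    return {g for g, t in tiers.items() if _TIER_RANK[t] >= cut}


def _limits(
    expressed: set[str], code: HoxCode
) -> tuple[AxisPosition, AxisPosition] | None:
    """Interval supported by one evidence tier, or None if nothing expressed.

    Anterior limit: the minimum over expressed markers of their anterior
    positions (brain markers resolve by anteriority — Foxg1 to the FB,
    Otx2 to the MB, En2 to the HB — so the most anterior expressed marker
    wins; Hox genes contribute their class boundary positions).  Posterior
    limit: the maximum over expressed markers of their posterior extents.
    Since every gene's boundary precedes its extent, the interval is always
    well ordered, and min/max aggregation makes both limits monotone in
    every gene's expression.
    """
    positions = code.gene_positions
    anterior_candidates = []
    posterior_candidates = []
    for m in code.brain_markers:
        if m in expressed:
            anterior_candidates.append(code.brain_anterior_limit[m])
            posterior_candidates.append(code.brain_posterior_span[m])
    for g in expressed:
        if g in positions:
            boundary, extent = positions[g]
            anterior_candidates.append(boundary)
            posterior_candidates.append(extent)
    if not anterior_candidates:
        return None
    return min(anterior_candidates), max(posterior_candidates)


def classify_ap(
    tiers: dict[str, str], code: HoxCode | None = None, sample: str = "sample"
) -> RegionCall:
    """Call the A/P coverage interval of one sample from its tier profile.

    Genes absent from ``tiers`` are treated as off (and logged).  High-tier
    genes define the core interval; genes at low tier or above define the
    extended interval, which therefore always contains the core.
    """
    code = code or HoxCode()
    for t in tiers.values():
        if t not in _TIER_RANK:
            raise ValueError(f"unknown tier {t!r}")
    missing = [g for g in code.all_genes if g not in tiers]
    if missing:
        logger.info("%s: %d code gene(s) missing from profile, treated as off", sample, len(missing))

    known = set(code.all_genes)
    evidence = {g: t for g, t in tiers.items() if g in known and t != "off"}
    core = _limits(_expressed(tiers, "high") & known, code)
    # the >= low gene set contains the high set, so extended always
    # contains core by the min/max construction
    extended = _limits(_expressed(tiers, "low") & known, code)
    return RegionCall(sample=sample, core=core, extended=extended, evidence=evidence)


def classify_table(
    tiers: pd.DataFrame, code: HoxCode | None = None
) -> dict[str, RegionCall]:
    """Classify every sample (column) of a genes x samples tier table."""
    return {
        s: classify_ap(tiers[s].to_dict(), code=code, sample=s) for s in tiers.columns
    }


# --- dorsoventral coherence ------------------------------------------------


def dv_coherence(
    tiers: dict[str, str],
    code: dict[str, tuple[str, ...]] | None = None,
    sample: str = "sample",
) -> DVCall:
    """Check whether a tier profile supports a coherent dorsoventral identity.

    A class is *complete* when all of its marker TFs are at least low tier.
    A class expressed only partially generates an isolated-marker violation
    (e.g. Nkx2-2 without concurrent Nkx6-1 rules out a ventral call), and a
    complete intermediate class unaccompanied by dorsal Pax3/Pax7 is flagged
    as well — the call is the unique violation-free complete class, else
    ``"ambiguous"``.
    """
    code = code or DV_CODE
    if not code or any(not genes for genes in code.values()):
        raise ValueError("dorsoventral code must have non-empty marker sets")
    expressed = _expressed(tiers, "low")

    complete, violations = [], []
    for cls, genes in code.items():
        present = [g for g in genes if g in expressed]
        absent = [g for g in genes if g not in expressed]
        if not absent:
            complete.append(cls)
        elif present:
            violations.append(
                f"{cls}: {'/'.join(present)} expressed without concurrent {'/'.join(absent)}"
            )
    inter_expressed = (
        [g for g in code.get("intermediate", ()) if g in expressed]
        if "intermediate" in code
        else []
    )
    if inter_expressed and "dorsal" in code and not expressed & set(code["dorsal"]):
        violations.append(
            "intermediate: "
            + "/".join(inter_expressed)
            + " unaccompanied by dorsal "
            + "/".join(code["dorsal"])
        )
        if "intermediate" in complete:
            complete.remove("intermediate")

    if len(complete) == 1 and not violations:
        call = complete[0]
    else:
        call = "ambiguous"
    return DVCall(
        sample=sample,
        call=call,
        complete_classes=tuple(complete),
        violations=tuple(violations),
    )
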