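"""Anteroposterior axis model, Hox class code, and dorsoventral code tables.

The central nervous system's anteroposterior (A/P) axis is modelled as the
ordered domains forebrain (FB) < midbrain (MB) < hindbrain (HB) < cervical
spinal cord (CSC) < thoracic (TSC) < lumbar (LSC) < caudal, each split into
an anterior and a posterior half.  Hox genes are grouped into classes by the
domain holding their anterior expression boundary; brain markers (Foxg1,
Otx2, En2) cover the pre-Hox territory.  The tables below ship the default
code; every table is plain data and can be replaced by the caller (e.g. from
a YAML file, see :func:`axiscope.io.load_code_yaml`).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

DOMAINS: tuple[str, ...] = ("FB", "MB", "HB", "CSC", "TSC", "LSC", "caudal")

ANTERIOR = "anterior"
POSTERIOR = "posterior"

TIERS: tuple[str, ...] = ("off", "low", "high")


@functools.total_ordering
@dataclass(frozen=True)
class AxisPosition:
    """A half-domain position on the A/P axis, totally ordered head to tail."""

    domain: str
    half: str = ANTERIOR

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown axis domain {self.domain!r}")
        if self.half not in (ANTERIOR, POSTERIOR):
            raise ValueError(f"half must be 'anterior' or 'posterior', got {self.half!r}")

    @property
    def rank(self) -> int:
        return 2 * DOMAINS.index(self.domain) + (self.half == POSTERIOR)

    def __lt__(self, other: "AxisPosition") -> bool:
        return self.rank < other.rank

    def __str__(self) -> str:
        return f"{self.half} {self.domain}"


#: Hox classes keyed by the axis domain of their anterior expression boundary.
#: HB class: Hoxa1-a4 and Hoxb1-b4 (anterior boundary in the hindbrain).
#: CSC class: Hoxa5, Hoxb5, Hoxb6 (boundary in the cervical cord; Hoxa5's
#: boundary lies anterior to Hoxb5's).  TSC class: Hoxa6, a7, a9, a10 and
#: Hoxb7-b9 (b7-b9 boundaries near the CSC/TSC junction) plus Hoxc9.
#: Hoxc10/Hoxc11 are expressed from the lumbar cord posteriorly; Hoxa13 and
#: Hoxb13 mark the caudal-most cord.
HOX_CLASSES: dict[str, tuple[str, ...]] = {
    "HB": ("Hoxa1", "Hoxa2", "Hoxa3", "Hoxa4", "Hoxb1", "Hoxb2", "Hoxb3", "Hoxb4"),
    "CSC": ("Hoxa5", "Hoxb5", "Hoxb6"),
    "TSC": ("Hoxa6", "Hoxa7", "Hoxa9", "Hoxa10", "Hoxb7", "Hoxb8", "Hoxb9", "Hoxc9"),
    "LSC": ("Hoxc10", "Hoxc11"),
    "caudal": ("Hoxa13", "Hoxb13"),
}

#: Brain markers in anterior-to-posterior precedence, each mapped to the
#: anterior limit it supports when it is the most anterior expressed marker
#: (Foxg1: forebrain; Otx2 without Foxg1: midbrain; En2 alone: hindbrain)
#: and to the posterior end of its own expression span (En2 reaches only the
#: anterior hindbrain).
BRAIN_MARKERS: tuple[str, ...] = ("Foxg1", "Otx2", "En2")

BRAIN_ANTERIOR_LIMIT: dict[str, AxisPosition] = {
    "Foxg1": AxisPosition("FB", ANTERIOR),
    "Otx2": AxisPosition("MB", ANTERIOR),
    "En2": AxisPosition("HB", ANTERIOR),
}

BRAIN_POSTERIOR_SPAN: dict[str, AxisPosition] = {
    "Foxg1": AxisPosition("FB", POSTERIOR),
    "Otx2": AxisPosition("MB", POSTERIOR),
    "En2": AxisPosition("HB", ANTERIOR),
}


#: Per-gene refinements of the class-level positions, from the three
#: in-text anterior-boundary staggerings: Hoxa5's boundary lies in the
#: anterior CSC (anterior to Hoxb5's); Hoxa6/a7 and the CSC/TSC-junction
#: genes Hoxb7-b9 support only the anterior TSC (Hoxa9/a10 are needed for
#: the posterior TSC); Hoxc9 stays within the TSC while Hoxc10/c11 reach
#: from the lumbar cord posteriorly.
GENE_POSITION_OVERRIDES: dict[str, tuple[AxisPosition, AxisPosition]] = {
    "Hoxa5": (AxisPosition("CSC", ANTERIOR), AxisPosition("CSC", ANTERIOR)),
    **{
        g: (AxisPosition("TSC", ANTERIOR), AxisPosition("TSC", ANTERIOR))
        for g in ("Hoxa6", "Hoxa7", "Hoxb7", "Hoxb8", "Hoxb9")
    },
    **{
        g: (AxisPosition("LSC", ANTERIOR), AxisPosition("LSC", POSTERIOR))
        for g in ("Hoxc10", "Hoxc11")
    },
    **{
        g: (AxisPosition("caudal", ANTERIOR), AxisPosition("caudal", POSTERIOR))
        for g in ("Hoxa13", "Hoxb13")
    },
}


@dataclass(frozen=True)
class HoxCode:
    """Gene -> A/P position lookup used by the regional classifier.

    Each Hox gene carries an (anterior boundary, posterior extent) pair of
    axis positions derived from its class — by default the posterior half
    of the class's boundary domain for both, refined by the staggering
    overrides above.  A sample's coverage interval is the min boundary /
    max extent over its expressed genes, so the classifier is monotone in
    every gene's tier by construction.
    """

    classes: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(HOX_CLASSES))
    brain_markers: tuple[str, ...] = BRAIN_MARKERS
    brain_anterior_limit: dict[str, AxisPosition] = field(
        default_factory=lambda: dict(BRAIN_ANTERIOR_LIMIT)
    )
    brain_posterior_span: dict[str, AxisPosition] = field(
        default_factory=lambda: dict(BRAIN_POSTERIOR_SPAN)
    )
    position_overrides: dict[str, tuple[AxisPosition, AxisPosition]] = field(
        default_factory=lambda: dict(GENE_POSITION_OVERRIDES)
    )

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls, genes in self.classes.items():
            if cls not in DOMAINS:
                raise ValueError(f"Hox class {cls!r} is not an axis domain")
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g} assigned to both {seen[g]} and {cls}")
                seen[g] = cls

    @property
    def gene_class(self) -> dict[str, str]:
        return {g: cls for cls, genes in self.classes.items() for g in genes}

    @property
    def gene_positions(self) -> dict[str, tuple[AxisPosition, AxisPosition]]:
        """(anterior boundary, posterior extent) for every Hox gene."""
        out = {}
        for cls, genes in self.classes.items():
            default = AxisPosition(cls, POSTERIOR)
            for g in genes:
                out[g] = self.position_overrides.get(g, (default, default))
        return out

    @property
    def hox_genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.classes.values() for g in genes)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.brain_markers + self.hox_genes


#: Dorsoventral neural-tube code: each class is called only when its full
#: marker set is expressed.  A standard progenitor-domain code; configurable.
DV_CODE: dict[str, tuple[str, ...]] = {
    "dorsal": ("Pax3", "Pax7", "Olig3"),
    "intermediate": ("Irx3", "Irx5", "Dbx1", "Dbx2", "Pax6"),
    "ventral": ("Nkx6-1", "Nkx2-2", "Olig2"),
}


def default_hox_code() -> HoxCode:
    return HoxCode()


# --- the six NSC lines' bulk expression-tier code -------------------------
#
# Tier profile of each line over the brain markers and Hox genes, as read
# from the microarray comparison of the six EpiSC-derived NSC lines:
#   XN4  Foxg1 high, Otx2/En2 low, no Hox             -> forebrain
#   XN1  Otx2/En2 + HB class + Hoxa5 (not Hoxb5) high -> MB to anterior CSC
#   KN3  En2 + HB class high, CSC/TSC classes low     -> HB core + extension
#   KN1  HB+CSC classes, a6-7, b7-9 high; a9/a10 off  -> post. HB/CSC - ant. TSC
#   CN1  HB/CSC/TSC incl. a9, a10, c9 high; c10 off   -> posterior limit TSC
#   CN4  as CN1
NSC_LINES: tuple[str, ...] = ("XN4", "XN1", "KN3", "KN1", "CN1", "CN4")


def _line_code() -> dict[str, dict[str, str]]:
    hb = HOX_CLASSES["HB"]
    csc = HOX_CLASSES["CSC"]
    tsc_early = ("Hoxa6", "Hoxa7", "Hoxb7", "Hoxb8", "Hoxb9")
    tsc_late = ("Hoxa9", "Hoxa10", "Hoxc9")
    all_genes = BRAIN_MARKERS + tuple(g for gs in HOX_CLASSES.values() for g in gs)

    def profile(**tiers: str) -> dict[str, str]:
        out = {g: "off" for g in all_genes}
        out.update(tiers)
        return out

    return {
        "XN4": profile(Foxg1="high", Otx2="low", En2="low"),
        "XN1": profile(
            Otx2="high", En2="high", **{g: "high" for g in hb}, Hoxa5="high"
        ),
        "KN3": profile(
            En2="high",
            **{g: "high" for g in hb},
            **{g: "low" for g in csc},
            **{g: "low" for g in tsc_early},
        ),
        "KN1": profile(
            **{g: "high" for g in hb},
            **{g: "high" for g in csc},
            **{g: "high" for g in tsc_early},
        ),
        "CN1": profile(
            **{g: "high" for g in hb},
            **{g: "high" for g in csc},
            **{g: "high" for g in tsc_early},
            **{g: "high" for g in tsc_late},
        ),
        "CN4": profile(
            **{g: "high" for g in hb},
            **{g: "high" for g in csc},
            **{g: "high" for g in tsc_early},
            **{g: "high" for g in tsc_late},
        ),
    }


#: sample -> gene -> tier, for the six NSC lines.
LINE_TIER_CODE: dict[str, dict[str, str]] = _line_code()
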