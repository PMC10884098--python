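"""Readers, writers, gene filtering, cell sampling and configuration.

Count matrices are exchanged either as a MatrixMarket directory
(``matrix.mtx`` genes x cells, with ``genes.tsv`` and ``barcodes.tsv``
sidecars) or as a single wide TSV (genes as rows, cells as columns).
Tracks travel as CSV with the header
``cell_id,group,frame,t_min,x_um,y_um``; bulk tables as TSV with
``<sample>_<replicate>`` columns.  Config files are YAML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .codes import DV_CODE, HOX_CLASSES, AxisPosition, HoxCode
from .migration import TRACK_COLUMNS
from .types import CountMatrix

logger = logging.getLogger(__name__)

#: Default prefixes of genes removed before single-cell analysis:
#: mitochondrial ("mt-") and ribosomal protein ("Rps", "Rpl") genes.
DEFAULT_DROP_PREFIXES: tuple[str, ...] = ("mt-", "Rps", "Rpl")


# --- counts ----------------------------------------------------------------


def write_counts_mtx(counts: CountMatrix, out_dir: str | Path) -> Path:
    """Write a MatrixMarket directory: matrix.mtx + genes.tsv + barcodes.tsv.

    ``barcodes.tsv`` carries cell metadata columns (e.g. the recorded depth
    multiplier) alongside the barcode.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csc_matrix(counts.X))
    pd.Series(counts.genes, name="gene").to_csv(
        out / "genes.tsv", sep="\t", index=False, header=False
    )
    meta = counts.cell_meta if counts.cell_meta is not None else pd.DataFrame(index=counts.cells)
    meta = meta.copy()
    meta.insert(0, "barcode", counts.cells)
    meta.to_csv(out / "barcodes.tsv", sep="\t", index=False)
    return out


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    counts.to_frame().to_csv(path, sep="\t")
    return path


def _dedupe_genes(genes: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in genes:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    n_dup = len(genes) - len(seen)
    if n_dup:
        logger.warning("disambiguated %d duplicate gene symbol(s) with suffixes", n_dup)
    return out


def read_counts(path: str | Path, fmt: str | None = None, line: str | None = None) -> CountMatrix:
    """Read a count matrix from an MTX directory or a wide TSV.

    ``fmt`` is inferred from the path when omitted: a directory (or a
    ``.mtx`` file) means MatrixMarket, anything else a wide TSV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "mtx" if path.is_dir() or path.suffix == ".mtx" else "tsv"

    if fmt == "mtx":
        mtx_dir = path if path.is_dir() else path.parent
        try:
            X = np.asarray(spio.mmread(mtx_dir / "matrix.mtx").todense())
        except Exception as exc:  # scipy raises bare ValueError on bad files
            raise ValueError(f"malformed MatrixMarket file in {mtx_dir}: {exc}") from exc
        genes = pd.read_csv(mtx_dir / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(mtx_dir / "barcodes.tsv", sep="\t")
        cells = barcodes["barcode"].astype(str).tolist()
        meta = barcodes.drop(columns=["barcode"])
        meta.index = pd.Index(cells)
        cell_meta = meta if len(meta.columns) else None
    elif fmt == "tsv":
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty counts file: {path}") from exc
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed counts TSV {path}: {exc}") from exc
        if frame.empty:
            raise ValueError(f"counts table {path} has no data")
        genes = [str(g) for g in frame.index]
        cells = [str(c) for c in frame.columns]
        X = frame.to_numpy()
        cell_meta = None
    else:
        raise ValueError(f"unknown counts format {fmt!r}")

    if np.asarray(X).min(initial=0) < 0:
        raise ValueError("count matrix contains negative entries")
    return CountMatrix(
        genes=_dedupe_genes([str(g) for g in genes]),
        cells=[str(c) for c in cells],
        X=np.asarray(X, dtype=np.int64),
        cell_meta=cell_meta,
        line=line,
    )


def filter_genes(
    counts: CountMatrix, drop_prefixes: tuple[str, ...] = DEFAULT_DROP_PREFIXES
) -> CountMatrix:
    """Drop genes whose symbol starts with any prefix (case-insensitive)."""
    if not drop_prefixes:
        raise ValueError("drop_prefixes must be non-empty")
    lowered = tuple(p.lower() for p in drop_prefixes)
    keep = [g for g in counts.genes if not g.lower().startswith(lowered)]
    removed = counts.n_genes - len(keep)
    if not keep:
        raise ValueError("gene filter removed every gene")
    if removed:
        logger.info("removed %d gene(s) matching prefixes %s", removed, drop_prefixes)
    return counts.subset_genes(keep)


def sample_cells(
    counts: CountMatrix, n: int = 4000, seed: int | np.random.Generator = 0
) -> CountMatrix:
    """Uniform random subset of n cells without replacement (order preserved).

    When fewer than n cells are available all cells are kept and a warning
    is logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n >= counts.n_cells:
        if n > counts.n_cells:
            logger.warning(
                "requested %d cells but only %d available; keeping all", n, counts.n_cells
            )
        return counts.subset_cells(np.arange(counts.n_cells))
    idx = np.sort(rng.choice(counts.n_cells, size=n, replace=False))
    return counts.subset_cells(idx)


# --- tracks and bulk tables ------------------------------------------------


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    tracks[list(TRACK_COLUMNS)].to_csv(path, index=False)
    return path


def read_tracks(path: str | Path) -> pd.DataFrame:
    tracks = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise ValueError(f"track table {path} lacks column(s): {sorted(missing)}")
    bad = ~np.isfinite(tracks[["x_um", "y_um", "t_min"]].to_numpy()).all(axis=1)
    if bad.any():
        raise ValueError(f"track table {path} has non-finite coordinates")
    return tracks


def write_bulk(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t")
    return path


def read_bulk(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.to_numpy() < 0).any():
        raise ValueError(f"bulk table {path} has negative intensities")
    return table


# --- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def load_code_yaml(path: str | Path | None = None) -> tuple[HoxCode, dict]:
    """Load Hox / dorsoventral code tables from YAML, or the shipped defaults.

    Expected YAML shape::

        hox_classes: {HB: [Hoxa1, ...], CSC: [...], ...}
        dv_code: {dorsal: [...], intermediate: [...], ventral: [...]}
    """
    if path is None:
        return HoxCode(), {k: tuple(v) for k, v in DV_CODE.items()}
    cfg = load_config(path)
    classes = {k: tuple(v) for k, v in cfg.get("hox_classes", HOX_CLASSES).items()}
    dv = {k: tuple(v) for k, v in cfg.get("dv_code", DV_CODE).items()}
    return HoxCode(classes=classes), dv


def region_call_json(call) -> dict:
    """JSON-ready form of a RegionCall."""

    def pos(p: AxisPosition | None):
        return None if p is None else {"domain": p.domain, "half": p.half}

    return {
        "sample": call.sample,
        "undetermined": call.undetermined,
        "core": None if call.core is None else [pos(call.core[0]), pos(call.core[1])],
        "extended": None
        if call.extended is None
        else [pos(call.extended[0]), pos(call.extended[1])],
        "evidence": call.evidence,
    }


# --- optional rendering ------------------------------------------------------


def render_quiver_svg(
    field, path: str | Path, um_per_speed: float = 500.0 / 300.0
) -> Path:
    """Render a velocity field as an SVG quiver plot (requires matplotlib).

    Arrow lengths follow the convention that a migration rate of 300 µm/h
    is drawn as a 500 µm arrow (``um_per_speed`` µm of plot length per
    µm/h of speed).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pop = field.populated
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.quiver(
        pop["gx"], pop["gy"], pop["vx"] * um_per_speed, pop["vy"] * um_per_speed,
        angles="xy", scale_units="xy", scale=1.0, width=0.004,
    )
    ax.set_aspect("equal")
    ax.invert_yaxis()  # +y = posterior, drawn downward
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm; posterior down)")
    path = Path(path)
    fig.savefig(path, format="svg")
    plt.close(fig)
    return path
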