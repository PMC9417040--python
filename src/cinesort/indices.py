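"""Adjacent-slice residual-motion-artifact (RMA) indices.

Six indicators of the consistency of two CT slices that face each other
across a couch-position boundary:

* ``ncc`` — Pearson-type normalised cross-correlation of in-mask pixels
  (close to 1 when the breathing states match);
* ``rmsd`` — root-mean-square deviation on intensities min–max rescaled to
  [0, 1] over the union body mask (close to 0 when matched);
* ``dcc`` — data-consistency ratio ``min(D_N, D_N+1)/max(D_N, D_N+1)`` of
  the total in-mask attenuation sums. The zeroth moment of a parallel-beam
  projection is angle independent, so the projection integral reduces to the
  area integral of the slice — a cheap consistency condition that two slices
  of one static object must satisfy;
* ``n_ncc`` / ``n_rmsd`` / ``n_dcc`` — the same quantities normalised by the
  within-block adjacent-slice indices on either side of the boundary, which
  removes the body-part dependence of the raw values.

All statistics are computed only within the patient body region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import (
    CineSortError,
    ConfigError,
    MaskError,
    ZeroDenominatorError,
    ZeroVarianceError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_NAMES",
    "BoundaryContext",
    "IndexTable",
    "body_mask",
    "ncc",
    "rmsd",
    "dcc",
    "normalised_index",
    "error_form",
    "build_index_table",
]

INDEX_NAMES = ("ncc", "rmsd", "dcc", "n_ncc", "n_rmsd", "n_dcc")

#: HU-like threshold separating air background from the body.
DEFAULT_BODY_THRESHOLD = -400.0

#: Offset shifting HU-like values onto a nonnegative attenuation scale
#: (air ~ -1000 -> ~0) before summing for the data-consistency ratio.
DCC_OFFSET = 1000.0


def body_mask(image: np.ndarray, threshold: float = DEFAULT_BODY_THRESHOLD) -> np.ndarray:
    """Patient body region: threshold, largest connected component, fill holes."""
    raw = np.asarray(image) > threshold
    if not raw.any():
        raise MaskError("no pixels above body threshold: empty mask")
    labels = measure.label(raw)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(largest)


def _shared_mask(a, b, mask, threshold):
    if mask is None:
        mask = body_mask(a, threshold) & body_mask(b, threshold)
    if not mask.any():
        raise MaskError("shared mask is empty")
    return mask


def ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
        threshold: float = DEFAULT_BODY_THRESHOLD) -> float:
    """Normalised cross-correlation over the shared body mask.

    Range [-1, 1]; not clipped (a perfectly inverted slice scores -1).
    """
    mask = _shared_mask(a, b, mask, threshold)
    va = np.asarray(a, dtype=float)[mask]
    vb = np.asarray(b, dtype=float)[mask]
    da = va - va.mean()
    db = vb - vb.mean()
    ssa = float(np.dot(da, da))
    ssb = float(np.dot(db, db))
    if ssa == 0.0 or ssb == 0.0:
        raise ZeroVarianceError("zero in-mask variance: NCC undefined")
    return float(np.dot(da, db) / np.sqrt(ssa * ssb))


def rmsd(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
         threshold: float = DEFAULT_BODY_THRESHOLD, rescale: bool = True) -> float:
    """Root-mean-square deviation over the shared mask.

    With ``rescale`` (default) both slices are min–max mapped to [0, 1] using
    the joint intensity range over the union of the two body masks, making
    the value dimensionless; ``rescale=False`` gives raw HU-like units.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mask is None:
        ma = body_mask(a, threshold)
        mb = body_mask(b, threshold)
        mask, union = ma & mb, ma | mb
    else:
        union = mask
    if not mask.any():
        raise MaskError("shared mask is empty")
    if rescale:
        vals = np.concatenate([a[union], b[union]])
        lo, hi = float(vals.min()), float(vals.max())
        scale = hi - lo if hi > lo else 1.0
        a = (a - lo) / scale
        b = (b - lo) / scale
    diff = a[mask] - b[mask]
    return float(np.sqrt(np.mean(diff**2)))


def dcc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None,
        threshold: float = DEFAULT_BODY_THRESHOLD, offset: float = DCC_OFFSET) -> float:
    """Data-consistency ratio of total in-mask attenuation, in (0, 1]."""
    mask = _shared_mask(a, b, mask, threshold)
    da = float(np.sum(np.asarray(a, dtype=float)[mask] + offset))
    db = float(np.sum(np.asarray(b, dtype=float)[mask] + offset))
    if da <= 0 or db <= 0:
        raise ZeroDenominatorError("nonpositive attenuation sum: DCC undefined")
    return min(da, db) / max(da, db)


_BASE_FUNCS = {"ncc": ncc, "rmsd": rmsd, "dcc": dcc}


@dataclass(frozen=True)
class BoundaryContext:
    """The four slices flanking a couch-position boundary.

    ``upper_penultimate`` / ``upper_last`` are the last two slices of the
    block at couch N; ``lower_first`` / ``lower_second`` the first two of the
    block at couch N+1. The boundary pair is (upper_last, lower_first); the
    two within-block pairs provide the normalisation denominator.
    """

    upper_penultimate: np.ndarray
    upper_last: np.ndarray
    lower_first: np.ndarray
    lower_second: np.ndarray

    def __post_init__(self) -> None:
        shape = self.upper_last.shape
        for s in (self.upper_penultimate, self.lower_first, self.lower_second):
            if s.shape != shape:
                raise ConfigError("all four context slices must share a grid shape")

    @classmethod
    def from_blocks(cls, upper_block: np.ndarray, lower_block: np.ndarray) -> "BoundaryContext":
        if upper_block.shape[0] < 2 or lower_block.shape[0] < 2:
            raise ConfigError("blocks need >= 2 slices for a boundary context")
        return cls(upper_block[-2], upper_block[-1], lower_block[0], lower_block[1])


def normalised_index(
    ctx: BoundaryContext,
    base: str = "rmsd",
    roi: np.ndarray | None = None,
    threshold: float = DEFAULT_BODY_THRESHOLD,
) -> float:
    """Boundary index normalised by within-block adjacent-slice indices.

    ``ratio = Index(upper_last, lower_first) /
    mean(Index(upper_penult, upper_last), Index(lower_first, lower_second))``.

    For ``base="rmsd"`` the returned N-RMSD is ``|ratio - 1|``, so
    artifact-free data scores ~0 while the NCC/DCC ratios score ~1. An
    optional ``roi`` restricts every pairwise mask (evaluation band).
    """
    if base not in _BASE_FUNCS:
        raise ConfigError(f"unknown base index {base!r}")
    fn = _BASE_FUNCS[base]

    def pair(a, b):
        mask = body_mask(a, threshold) & body_mask(b, threshold)
        if roi is not None:
            mask = mask & roi
        if not mask.any():
            raise MaskError("empty pairwise mask in boundary context")
        return fn(a, b, mask=mask)

    boundary = pair(ctx.upper_last, ctx.lower_first)
    denom = 0.5 * (pair(ctx.upper_penultimate, ctx.upper_last)
                   + pair(ctx.lower_first, ctx.lower_second))
    if denom == 0.0:
        raise ZeroDenominatorError("within-block indices average to zero")
    ratio = boundary / denom
    return abs(ratio - 1.0) if base == "rmsd" else ratio


def error_form(name: str, value: float) -> float:
    """Map an index value onto the [0, 1] error scale (0 = artifact free).

    N-RMSD is already a deviation and is clipped to [0, 1]; similarity-type
    indices (NCC/DCC families, ideal value 1) become ``1 - min(value, 1)``.
    """
    if name in ("rmsd", "n_rmsd"):
        return float(np.clip(value, 0.0, 1.0))
    if name in ("ncc", "dcc", "n_ncc", "n_dcc"):
        return float(np.clip(1.0 - min(value, 1.0), 0.0, 1.0))
    raise ConfigError(f"unknown index name {name!r}")


@dataclass
class IndexTable:
    """Pairwise boundary lookup table.

    ``values[b, j, k]`` is the index for candidate j at couch b against
    candidate k at couch b+1; NaN marks entries whose computation failed
    (these are treated as worst case, 1.0, during sorting).
    """

    index: str
    values: np.ndarray          # (n-1, m, m)
    n_missing: int = 0

    @property
    def n_entries(self) -> int:
        return int(self.values.size)

    def error_values(self) -> np.ndarray:
        out = np.empty_like(self.values)
        flat_in = self.values.ravel()
        flat_out = out.ravel()
        for i, v in enumerate(flat_in):
            flat_out[i] = 1.0 if np.isnan(v) else error_form(self.index, float(v))
        return out

    def to_frame(self) -> pd.DataFrame:
        nb, m, _ = self.values.shape
        b, j, k = np.meshgrid(np.arange(nb), np.arange(m), np.arange(m),
                              indexing="ij")
        return pd.DataFrame({
            "boundary": b.ravel(),
            "j": j.ravel(),
            "k": k.ravel(),
            "index_name": self.index,
            "value": self.values.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "IndexTable":
        df = pd.read_csv(path)
        name = str(df["index_name"].iloc[0])
        nb = int(df["boundary"].max()) + 1
        m = int(df["j"].max()) + 1
        values = np.full((nb, m, m), np.nan)
        values[df["boundary"], df["j"], df["k"]] = df["value"]
        return cls(index=name, values=values,
                   n_missing=int(np.isnan(values).sum()))


def build_index_table(study, index: str = "n_rmsd",
                      threshold: float = DEFAULT_BODY_THRESHOLD) -> IndexTable:
    """Tabulate the chosen index for every boundary candidate pair.

    There are exactly m^2 x (n - 1) entries: the index only couples the
    candidate choices of the two couch positions flanking each boundary, so
    no other combination needs to be evaluated. Failed entries are recorded
    as NaN and counted, never dropped.
    """
    if index not in INDEX_NAMES:
        raise ConfigError(f"unknown index {index!r}; choose from {INDEX_NAMES}")
    blocks = study.blocks
    n, m = blocks.shape[:2]
    if n < 2:
        raise ConfigError("need >= 2 couch positions to build an index table")
    normalised = index.startswith("n_")
    base = index.removeprefix("n_")
    fn = _BASE_FUNCS[base]

    masks: dict[tuple, np.ndarray] = {}

    def mask_of(i, j, which):
        key = (i, j, which)
        if key not in masks:
            sl = blocks[i, j, -1] if which == "tail" else blocks[i, j, 0]
            masks[key] = body_mask(sl, threshold)
        return masks[key]

    within: dict[tuple, float] = {}

    def within_index(i, j, which):
        # adjacent-slice index of the last (tail) or first (head) pair of a block
        key = (i, j, which)
        if key not in within:
            if which == "tail":
                a, b = blocks[i, j, -2], blocks[i, j, -1]
            else:
                a, b = blocks[i, j, 0], blocks[i, j, 1]
            within[key] = fn(a, b, mask=body_mask(a, threshold) & body_mask(b, threshold))
        return within[key]

    values = np.full((n - 1, m, m), np.nan)
    missing = 0
    for b in range(n - 1):
        for j in range(m):
            tail = blocks[b, j, -1]
            tail_mask = mask_of(b, j, "tail")
            for k in range(m):
                try:
                    head = blocks[b + 1, k, 0]
                    pm = tail_mask & mask_of(b + 1, k, "head")
                    if not pm.any():
                        raise MaskError("empty boundary mask")
                    boundary = fn(tail, head, mask=pm)
                    if normalised:
                        denom = 0.5 * (within_index(b, j, "tail")
                                       + within_index(b + 1, k, "head"))
                        if denom == 0.0:
                            raise ZeroDenominatorError("zero denominator")
                        ratio = boundary / denom
                        values[b, j, k] = abs(ratio - 1.0) if base == "rmsd" else ratio
                    else:
                        values[b, j, k] = boundary
                except CineSortError as exc:
                    missing += 1
                    logger.debug("table entry (%d,%d,%d) failed: %s", b, j, k, exc)
    if missing:
        logger.warning("%d/%d index-table entries failed and are marked missing",
                       missing, values.size)
    return IndexTable(index=index, values=values, n_missing=missing)
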