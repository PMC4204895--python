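"""Time-series expression matrices: loading, floor truncation, normalization,
linear interpolation.

Expression values are in arbitrary units (a.u.) after upstream array
normalization; very low values are unreliable, so matrices are truncated
from below at a floor (default 20 a.u.).  Times are in days relative to the
induction of differentiation (day 0); negative days (proliferating cells)
are allowed.  Sparse grids (e.g. a mouse-style day −2, 0, 2, 7 course) are
densified by piecewise-linear interpolation — never extrapolation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateGeneError,
    EmptyInputError,
    ExtrapolationError,
    InsufficientDataError,
    ParseError,
)

DEFAULT_FLOOR = 20.0


@dataclass
class ExpressionSeries:
    """A gene × timepoint expression matrix with day coordinates.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row of ``values``.
    times : ndarray
        Strictly increasing sampling days (may be negative), length ≥ 2.
    values : ndarray, shape (n_genes, n_times)
        Non-negative expression levels (a.u.), floor-truncated.
    floor : float
        Lower truncation bound applied to ``values``.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    floor: float = DEFAULT_FLOOR
    interpolated_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InsufficientDataError(
                f"need >= 2 timepoints, got {self.times.size}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ParseError("times must be strictly increasing")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise DuplicateGeneError("duplicate gene id in series")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ParseError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite expression value")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def level(self, gene: str, t: float) -> float:
        """Expression of ``gene`` at day ``t`` (exact at knots, linear between)."""
        idx = self.gene_index(gene)
        if t < self.times[0] or t > self.times[-1]:
            raise ExtrapolationError(f"t={t} outside [{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, self.values[idx]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.times)


def truncate_floor(values: np.ndarray, floor: float) -> np.ndarray:
    """Clip expression from below at ``floor`` (idempotent)."""
    return np.maximum(np.asarray(values, dtype=float), floor)


def _sniff_sep(path: str) -> str:
    with open(path, "r") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def load_expression(path: str, floor: float = DEFAULT_FLOOR) -> ExpressionSeries:
    """Read a delimited gene × day table and floor-truncate it.

    The first column holds gene ids; the header row holds numeric day
    labels (possibly negative).  TSV and CSV dialects are auto-detected.
    """
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read expression table {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"duplicated gene ids: {dups}")
    if df.shape[1] < 2:
        raise InsufficientDataError(f"{df.shape[1]} timepoints (< 2) in {path}")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"non-numeric day label in header: {exc}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[df.dtypes == object].tolist()
        raise ParseError(f"non-numeric cells in columns {bad}")
    if np.isnan(values).any():
        raise ParseError("missing/non-numeric cell in expression table")
    return ExpressionSeries(
        gene_ids=[str(g) for g in df.index],
        times=times,
        values=truncate_floor(values, floor),
        floor=floor,
    )


def write_expression(series: ExpressionSeries, path: str, sep: str = "\t") -> None:
    """Write a series back in the same gene × day table dialect."""
    df = series.to_frame()
    df.columns = [format(t, "g") for t in series.times]
    df.to_csv(path, sep=sep, index_label="gene")


def interpolate_series(
    series: ExpressionSeries, target_times: list[float] | np.ndarray
) -> ExpressionSeries:
    """Densify a series onto ``target_times`` by per-gene linear interpolation.

    Existing timepoints are preserved exactly; no extrapolation — any
    target outside the observed range raises :class:`ExtrapolationError`.
    The returned series carries an ``interpolated_mask`` flagging columns
    that were not observed, so downstream residuals can exclude them.
    """
    target = np.asarray(target_times, dtype=float)
    if target.ndim != 1 or target.size < 2:
        raise InsufficientDataError("need >= 2 target times")
    if target.min() < series.times[0] or target.max() > series.times[-1]:
        raise ExtrapolationError(
            f"target range [{target.min()}, {target.max()}] exceeds observed "
            f"[{series.times[0]}, {series.times[-1]}]"
        )
    new_vals = np.vstack(
        [np.interp(target, series.times, row) for row in series.values]
    )
    observed = np.isin(target, series.times)
    return ExpressionSeries(
        gene_ids=list(series.gene_ids),
        times=target,
        values=new_vals,
        floor=series.floor,
        interpolated_mask=~observed,
    )


@dataclass
class ScaleRecord:
    """Per-feature factors of the modified feature scaling (invertible)."""

    factors: np.ndarray        # multiply raw row by factor = mean/std
    degenerate: np.ndarray     # True where std == 0 (row passed through)

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        out = np.array(normalized, dtype=float)
        ok = ~self.degenerate
        out[ok] = out[ok] / self.factors[ok, None]
        return out

    def to_text(self) -> str:
        lines = ["# feature\tfactor\tdegenerate"]
        for i, (f, d) in enumerate(zip(self.factors, self.degenerate)):
            lines.append(f"{i}\t{float(f):.17g}\t{int(d)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ScaleRecord":
        factors, degen = [], []
        for line in io.StringIO(text):
            if not line.strip() or line.startswith("#"):
                continue
            _, f, d = line.split("\t")
            factors.append(float(f))
            degen.append(bool(int(d)))
        return cls(np.array(factors), np.array(degen, dtype=bool))


def normalize_features(matrix: np.ndarray) -> tuple[np.ndarray, ScaleRecord]:
    """Rescale each feature row x to x · mean(x)/std(x).

    This up-weights highly expressed features (instead of the usual
    autoscaling to unit variance), counteracting the information loss of
    floor truncation.  Sample (n−1) standard deviation is used.  Constant
    rows (std = 0, e.g. genes pinned at the floor) pass through unchanged
    and are flagged degenerate in the returned :class:`ScaleRecord`.
    """
    X = np.asarray(matrix, dtype=float)
    if X.size == 0:
        raise EmptyInputError("empty feature matrix")
    if X.ndim != 2 or X.shape[1] < 2:
        raise InsufficientDataError("each feature needs >= 2 samples")
    std = X.std(axis=1, ddof=1)
    mean = X.mean(axis=1)
    degenerate = std == 0.0
    factors = np.ones_like(std)
    ok = ~degenerate
    factors[ok] = mean[ok] / std[ok]
    return X * factors[:, None], ScaleRecord(factors=factors, degenerate=degenerate)
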