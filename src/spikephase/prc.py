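"""Tabulated infinitesimal phase-resetting curves (PRCs).

The infinitesimal PRC, Z(phi), gives the phase advance (in cycles) produced
per unit of injected charge (pA*ms) arriving at phase phi of the firing
cycle.  Estimation procedures tabulate Z at phase-bin centers; between
centers the curve is linearly interpolated, and the interpolation is pinned
to Z(0) = Z(1) = 0 so that charge arriving exactly at a spike has no effect.
Phases past 1 (a cell that has already fired) map to zero responsiveness.

Two parametric type-1 (everywhere nonnegative) families are provided as
ground-truth stand-ins for biophysically derived curves: a raised cosine and
a beta-density shape whose skew places the peak early or late in the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TabulatedPRC",
    "sensitivity",
    "centroid",
    "raised_cosine_prc",
    "beta_prc",
]


@dataclass(frozen=True)
class TabulatedPRC:
    """A PRC tabulated at phase-bin centers, interpolable on [0, 1].

    Parameters
    ----------
    bin_centers : array-like
        Strictly increasing phases in the open interval (0, 1).
    values : array-like
        Z at each center, in cycles per (pA*ms).
    standard_errors : array-like, optional
        One standard error per bin (same units as ``values``).
    r_squared : float, optional
        Multiple-regression R^2 of the fit that produced the table.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    standard_errors: np.ndarray | None = None
    r_squared: float | None = None
    # interpolation knots with the pinned endpoints, built once
    _knots: np.ndarray = field(init=False, repr=False, compare=False)
    _knot_values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        centers = np.asarray(self.bin_centers, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("bin_centers must be a non-empty 1-d array")
        if centers.size != values.size:
            raise ValueError("bin_centers and values must have equal length")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if centers[0] <= 0.0 or centers[-1] >= 1.0:
            raise ValueError("bin_centers must lie strictly inside (0, 1)")
        if not np.all(np.isfinite(values)):
            raise ValueError("PRC values must be finite")
        se = self.standard_errors
        if se is not None:
            se = np.asarray(se, dtype=float)
            if se.shape != values.shape:
                raise ValueError("standard_errors must match values in shape")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "standard_errors", se)
        object.__setattr__(
            self, "_knots", np.concatenate(([0.0], centers, [1.0]))
        )
        object.__setattr__(
            self, "_knot_values", np.concatenate(([0.0], values, [0.0]))
        )

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def knots(self) -> np.ndarray:
        """Interpolation knots: 0, the bin centers, 1."""
        return self._knots

    @property
    def knot_values(self) -> np.ndarray:
        """Z at the knots, with the pinned zeros at 0 and 1."""
        return self._knot_values

    def __call__(self, phi):
        """Evaluate the interpolated PRC at phase ``phi``.

        Piecewise linear through the bin centers with Z(0) = Z(1) = 0;
        phases beyond 1 return 0 (input is ineffective once the cell has
        fired).  Negative phases are invalid.
        """
        phi = np.asarray(phi, dtype=float)
        if np.any(phi < 0):
            raise ValueError("phase must be >= 0")
        out = np.interp(phi, self._knots, self._knot_values)
        return out if out.ndim else float(out)

    def sensitivity(self) -> float:
        """Integral of Z^2 over one cycle; see :func:`sensitivity`."""
        return sensitivity(self)

    def centroid(self) -> float:
        """First moment of the tabulated values; see :func:`centroid`."""
        return centroid(self)

    def rescaled_to_sensitivity(self, target: float) -> "TabulatedPRC":
        """Return a copy scaled so its sensitivity equals ``target``."""
        s = self.sensitivity()
        if s <= 0:
            raise ValueError("cannot rescale a PRC with zero sensitivity")
        factor = float(np.sqrt(target / s))
        se = None if self.standard_errors is None else self.standard_errors * factor
        return TabulatedPRC(self.bin_centers, self.values * factor, se, self.r_squared)

    # -- plain-text persistence (center, value[, se]) ----------------------

    def to_text(self, path) -> None:
        header = ["phase_center\tvalue" + ("\tse" if self.standard_errors is not None else "")]
        if self.r_squared is not None:
            header.insert(0, f"# r_squared={self.r_squared:.10g}")
        cols = [self.bin_centers, self.values]
        if self.standard_errors is not None:
            cols.append(self.standard_errors)
        body = "\n".join(
            "\t".join(f"{v:.12g}" for v in row) for row in zip(*cols)
        )
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n" + body + "\n")

    @classmethod
    def from_text(cls, path) -> "TabulatedPRC":
        r2 = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "r_squared=" in line:
                        r2 = float(line.split("r_squared=")[1])
                    continue
                if line[0].isalpha() or line.startswith("phase"):
                    continue  # column-name header
                rows.append([float(x) for x in line.replace(",", "\t").split("\t")])
        arr = np.asarray(rows, dtype=float)
        se = arr[:, 2] if arr.shape[1] > 2 else None
        return cls(arr[:, 0], arr[:, 1], se, r2)


def sensitivity(prc: TabulatedPRC) -> float:
    """Integral of the squared PRC over one cycle.

    Computed exactly on the pinned-endpoint piecewise-linear interpolant:
    on a segment where Z runs linearly from a to b over width h, the
    integral of Z^2 is h*(a^2 + a*b + b^2)/3.  Units:
    cycles^2/(pA^2*ms^2).  This scalar controls how strongly zero-mean
    current noise inflates spike-time variance.
    """
    x = prc.knots
    z = prc.knot_values
    h = np.diff(x)
    a, b = z[:-1], z[1:]
    return float(np.sum(h * (a * a + a * b + b * b) / 3.0))


def centroid(prc: TabulatedPRC) -> float:
    """First moment of the PRC: sum(phi_i * Z_i) / sum(Z_i) over bins.

    Summarises whether the cell's sensitivity peaks early (< 0.5) or late
    (> 0.5) in the interspike interval.
    """
    total = float(np.sum(prc.values))
    if total == 0.0:
        raise ValueError("centroid undefined for an all-zero PRC")
    return float(np.sum(prc.bin_centers * prc.values) / total)


def _bin_centers(n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) / n_bins


def raised_cosine_prc(
    amplitude: float | None = None,
    sensitivity_target: float | None = None,
    n_bins: int = 50,
) -> TabulatedPRC:
    """Symmetric type-1 PRC, Z(phi) = A*(1 - cos(2*pi*phi))/2.

    Exactly one of ``amplitude`` (peak value A, cycles per pA*ms) or
    ``sensitivity_target`` may be given; the analytic integral of the
    squared unit shape is 3/8, so A = sqrt(S_target / 0.375).
    """
    if (amplitude is None) == (sensitivity_target is None):
        raise ValueError("give exactly one of amplitude or sensitivity_target")
    if amplitude is None:
        amplitude = float(np.sqrt(sensitivity_target / 0.375))
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    phi = _bin_centers(n_bins)
    return TabulatedPRC(phi, amplitude * (1.0 - np.cos(2 * np.pi * phi)) / 2.0)


def beta_prc(
    p: float,
    q: float,
    amplitude: float | None = None,
    sensitivity_target: float | None = None,
    n_bins: int = 50,
) -> TabulatedPRC:
    """Skewed type-1 PRC, Z(phi) proportional to phi^p * (1-phi)^q.

    ``p < q`` peaks early in the cycle, ``p > q`` late (the repertoire of
    shapes seen across autonomously firing cells).  The shape is normalised
    to unit peak before scaling by ``amplitude``; alternatively the curve is
    rescaled to an exact ``sensitivity_target``.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    if (amplitude is None) == (sensitivity_target is None):
        raise ValueError("give exactly one of amplitude or sensitivity_target")
    phi = _bin_centers(n_bins)
    shape = phi**p * (1.0 - phi) ** q
    peak = (p / (p + q)) ** p * (q / (p + q)) ** q
    shape /= peak
    if amplitude is not None:
        if amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        return TabulatedPRC(phi, amplitude * shape)
    prc = TabulatedPRC(phi, shape)
    return prc.rescaled_to_sensitivity(sensitivity_target)
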