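"""Indel-spectrum decomposition of mixed Sanger chromatograms.

When a Cas9-edited sample is Sanger-sequenced, the chromatogram downstream
of the cut site is a superposition of the traces of every allele present:
an allele with net indel *k* contributes the control (wild-type) trace
shifted by *k* positions.  Decomposing the edited trace over shifted copies
of the control trace therefore yields the indel-size spectrum of the
sample — the approach popularised by the TIDE tool.

The decomposition window starts a few bases downstream of the cut (the
junction itself is heterogeneous) and the weights are obtained by
non-negative least squares, then normalised to fractions; goodness of fit
is reported as R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DegenerateInputError, InputError

CHANNELS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ChromatogramTrace:
    """Per-position four-channel peak intensities.

    ``channels`` has shape (4, L) in A, C, G, T order; positions are
    1-based and contiguous starting at ``start`` (default 1).
    """

    channels: np.ndarray
    start: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != 4:
            raise InputError("channels must have shape (4, L)")
        if (arr < 0).any():
            raise InputError("channel intensities must be non-negative")
        object.__setattr__(self, "channels", arr)

    @property
    def length(self) -> int:
        return self.channels.shape[1]

    @property
    def end(self) -> int:
        """Last covered 1-based position."""
        return self.start + self.length - 1

    def window(self, lo: int, hi: int) -> np.ndarray:
        """Channel block for 1-based positions lo..hi inclusive."""
        if lo < self.start or hi > self.end or lo > hi:
            raise InputError(f"window {lo}..{hi} outside trace coverage")
        i = lo - self.start
        return self.channels[:, i:i + (hi - lo + 1)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels.T, columns=list(CHANNELS))
        df.insert(0, "pos", np.arange(self.start, self.end + 1))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromatogramTrace":
        missing = {"pos", *CHANNELS} - set(df.columns)
        if missing:
            raise InputError(f"trace table missing columns: {sorted(missing)}")
        pos = df["pos"].to_numpy()
        if len(pos) == 0:
            raise InputError("empty trace table")
        if not (np.diff(pos) == 1).all():
            raise InputError("trace positions must be contiguous")
        return cls(df[list(CHANNELS)].to_numpy().T, start=int(pos[0]))


@dataclass(frozen=True)
class TraceSpectrum:
    """Decomposition result: fraction per indel size (shift).

    ``shifts`` are signed base-pair offsets (negative = deletion);
    ``fractions`` are the normalised non-negative weights; ``r_squared`` the
    goodness of fit over the decomposition window.
    """

    shifts: tuple[int, ...]
    fractions: tuple[float, ...]
    r_squared: float
    decomposition_window: tuple[int, int]

    def fraction_of(self, shift: int) -> float:
        try:
            return self.fractions[self.shifts.index(shift)]
        except ValueError:
            return 0.0

    @property
    def mode(self) -> int:
        return self.shifts[int(np.argmax(self.fractions))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shift": self.shifts, "fraction": self.fractions})

    def to_dict(self) -> dict:
        return {
            "shifts": list(self.shifts),
            "fractions": list(self.fractions),
            "r_squared": self.r_squared,
            "decomposition_window": list(self.decomposition_window),
        }


#: default window placement: skip the heterogeneous junction, then 50 bases
WINDOW_OFFSET = 5
WINDOW_LENGTH = 50


def decompose(
    control: ChromatogramTrace,
    edited: ChromatogramTrace,
    cut_site: int,
    max_shift: int = 10,
    window: tuple[int, int] | None = None,
) -> TraceSpectrum:
    """Decompose an edited trace over shifted control traces.

    For each shift k in [-max_shift, max_shift] the design column is the
    control trace displaced by k over the decomposition window (an allele
    with net indel k shows the control signal of position p-k at position
    p).  Non-negative least squares gives the weights, which are rounded to
    1e-6 and normalised to fractions; R² = 1 - SS_resid/SS_total over the
    window.

    ``cut_site`` is a 1-based trace position.  The default window is
    cut_site+5 .. cut_site+5+49, clipped so every shifted copy stays within
    both traces' coverage.
    """
    if max_shift < 1:
        raise InputError("max_shift must be >= 1")
    if window is None:
        lo = cut_site + WINDOW_OFFSET
        hi = lo + WINDOW_LENGTH - 1
        lo = max(lo, control.start + max_shift, edited.start)
        hi = min(hi, control.end - max_shift, edited.end)
        if hi < lo:
            raise InputError("no usable decomposition window within trace coverage")
    else:
        lo, hi = window
        if (lo - max_shift < control.start or hi + max_shift > control.end
                or lo < edited.start or hi > edited.end):
            raise InputError("window (± max_shift) outside trace coverage")

    if not control.window(lo, hi).any():
        raise DegenerateInputError("control trace is all zero over the window")

    shifts = list(range(-max_shift, max_shift + 1))
    design = np.column_stack([
        control.window(lo - k, hi - k).ravel() for k in shifts
    ])
    target = edited.window(lo, hi).ravel()

    weights, _ = nnls(design, target)
    weights = np.round(weights, 6)
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("decomposition assigned zero total weight")
    fractions = weights / total

    resid = target - design @ weights
    ss_res = float(resid @ resid)
    centered = target - target.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = min(1.0, max(0.0, r2))

    return TraceSpectrum(
        shifts=tuple(shifts),
        fractions=tuple(float(f) for f in fractions),
        r_squared=r2,
        decomposition_window=(lo, hi),
    )
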