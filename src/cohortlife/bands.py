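"""Age-band schemas for abridged life tables.

An abridged life table works on a small ordered set of age intervals
("bands") rather than single years of age.  Every band except the last is
closed with a finite width ``n`` (years); the last band is open-ended
(e.g. 65+).  Each band carries ``a``, the average fraction of the interval
lived by people who die inside it; 0.5 is the conventional assumption for
closed bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AgeBand", "AgeBandSchema", "DEFAULT_SCHEMA"]


@dataclass(frozen=True)
class AgeBand:
    """One age interval ``[start, start + width)``.

    ``width`` is ``math.inf`` for the terminal open band.  ``a`` is the
    fraction of the interval survived by those dying in it.
    """

    start: float
    width: float
    a: float = 0.5

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"band start must be >= 0, got {self.start}")
        if not self.width > 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")

    @property
    def is_open(self) -> bool:
        return math.isinf(self.width)

    @property
    def end(self) -> float:
        return self.start + self.width

    @property
    def label(self) -> str:
        if self.is_open:
            return f"{self.start:g}+"
        if float(self.start).is_integer() and float(self.width).is_integer():
            return f"{int(self.start)}-{int(self.end) - 1}"
        return f"[{self.start:g},{self.end:g})"

    def contains(self, age: float) -> bool:
        return self.start <= age < self.end


@dataclass(frozen=True)
class AgeBandSchema:
    """Ordered, contiguous age bands; exactly one open band, which is last."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.bands, tuple):
            object.__setattr__(self, "bands", tuple(self.bands))
        if len(self.bands) < 1:
            raise ValueError("schema needs at least one band")
        for j, band in enumerate(self.bands[:-1]):
            if band.is_open:
                raise ValueError("only the terminal band may be open-ended")
            nxt = self.bands[j + 1]
            if not math.isclose(band.end, nxt.start, abs_tol=1e-9):
                raise ValueError(
                    f"bands must be contiguous: {band.label} ends at {band.end}, "
                    f"next starts at {nxt.start}"
                )
        if not self.bands[-1].is_open:
            raise ValueError("the terminal band must be open-ended")

    @classmethod
    def from_uniform(
        cls,
        start: float = 20.0,
        terminal_start: float = 65.0,
        width: float = 5.0,
        a: float = 0.5,
    ) -> "AgeBandSchema":
        """Equal-width closed bands from ``start`` up to an open terminal band."""
        starts = np.arange(start, terminal_start, width)
        bands = [AgeBand(float(s), float(width), a) for s in starts]
        bands.append(AgeBand(float(terminal_start), math.inf, a))
        return cls(tuple(bands))

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterable[AgeBand]:
        return iter(self.bands)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bands], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return np.array([b.width for b in self.bands], dtype=float)

    @property
    def a_values(self) -> np.ndarray:
        return np.array([b.a for b in self.bands], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def min_age(self) -> float:
        return self.bands[0].start

    def index_of(self, age: float | Sequence[float] | np.ndarray):
        """Band index containing each exact age (half-open intervals).

        Raises ``ValueError`` for any age below the first band start.
        """
        arr = np.asarray(age, dtype=float)
        if np.any(arr < self.min_age):
            raise ValueError(
                f"age below schema start {self.min_age}: {arr[arr < self.min_age][:5]}"
            )
        idx = np.searchsorted(self.starts, arr, side="right") - 1
        if np.isscalar(age) or arr.ndim == 0:
            return int(idx)
        return idx.astype(int)


#: 5-year bands 20-24 ... 60-64 plus the open 65+ band, a = 0.5 throughout.
DEFAULT_SCHEMA = AgeBandSchema.from_uniform(20.0, 65.0, 5.0, 0.5)
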