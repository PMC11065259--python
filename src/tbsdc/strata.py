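"""Age/sex stratification shared by every country parameter block.

All model inputs are tabulated over the same eight strata: two sexes by four
age bands (15-24, 25-34, 35-44, 45-49 years). ``AgeSexTable`` is a thin,
immutable wrapper around a numpy array of shape ``(2, 4)`` — or ``(2, 4, n)``
once a parameter has been expanded to ``n`` Monte Carlo draws — so that the
deterministic pipeline and the draw-wise pipeline share one code path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

SEXES: tuple[str, ...] = ("male", "female")
AGE_BANDS: tuple[str, ...] = ("15-24", "25-34", "35-44", "45-49")

Cell = tuple[str, str]  # (sex, age_band)


class ValidationError(ValueError):
    """A fixture or table violates a domain invariant."""


def _canon_band(band: str) -> str:
    return band.replace("–", "-").strip()


@dataclass(frozen=True)
class AgeSexTable:
    """A value per (sex, age band) cell.

    Parameters
    ----------
    values
        Array of shape ``(2, 4)`` (rows: male, female; columns: the four age
        bands) or ``(2, 4, n_draws)`` for a draw-expanded parameter.
    """

    values: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim not in (2, 3) or arr.shape[:2] != (2, 4):
            raise ValidationError(
                f"expected shape (2, 4[, n]) over {SEXES} x {AGE_BANDS}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite cell value")
        if np.any(arr < 0):
            sex, band = self._first_offender(arr < 0)
            raise ValidationError(f"negative value in cell ({sex}, {band})")
        object.__setattr__(self, "values", arr)

    @staticmethod
    def _first_offender(mask: np.ndarray) -> Cell:
        idx = np.argwhere(mask)[0]
        return SEXES[idx[0]], AGE_BANDS[idx[1]]

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dict(cls, cells: Mapping[Cell, float]) -> "AgeSexTable":
        """Build from a mapping ``{(sex, age_band): value}`` (all 8 required)."""
        arr = np.empty((2, 4))
        seen = set()
        for (sex, band), v in cells.items():
            band = _canon_band(band)
            if sex not in SEXES or band not in AGE_BANDS:
                raise ValidationError(f"unknown cell ({sex}, {band})")
            arr[SEXES.index(sex), AGE_BANDS.index(band)] = v
            seen.add((sex, band))
        if len(seen) != 8:
            missing = [c for c in ((s, b) for s in SEXES for b in AGE_BANDS) if c not in seen]
            raise ValidationError(f"missing cell {missing[0]}")
        return cls(arr)

    @classmethod
    def constant(cls, value: float) -> "AgeSexTable":
        return cls(np.full((2, 4), float(value)))

    # -- accessors ----------------------------------------------------
    def cell(self, sex: str, band: str) -> float | np.ndarray:
        band = _canon_band(band)
        return self.values[SEXES.index(sex), AGE_BANDS.index(band)]

    def to_dict(self) -> dict[Cell, float]:
        return {
            (s, b): float(self.values[i, j])
            for i, s in enumerate(SEXES)
            for j, b in enumerate(AGE_BANDS)
        }

    def total(self) -> float | np.ndarray:
        """Sum over all 8 cells (the draw axis, if any, is preserved)."""
        out = self.values.sum(axis=(0, 1))
        return float(out) if np.ndim(out) == 0 else out

    # -- validation ---------------------------------------------------
    def require_proportion(self, name: str = "value") -> "AgeSexTable":
        if np.any(self.values > 1):
            sex, band = self._first_offender(self.values > 1)
            raise ValidationError(f"{name} > 1 in cell ({sex}, {band})")
        return self

    # -- arithmetic (cellwise, broadcasting over the draw axis) -------
    def _coerce(self, other) -> np.ndarray:
        if isinstance(other, AgeSexTable):
            return other.values
        return np.asarray(other, dtype=float)

    def __add__(self, other) -> "AgeSexTable":
        return AgeSexTable(self.values + self._coerce(other))

    def __mul__(self, other) -> "AgeSexTable":
        return AgeSexTable(self.values * self._coerce(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def minimum(self, other) -> "AgeSexTable":
        """Cellwise minimum (used for capping derived counts)."""
        return AgeSexTable(np.minimum(self.values, self._coerce(other)))

    def swap_sexes(self) -> "AgeSexTable":
        return AgeSexTable(self.values[::-1])

    @property
    def n_draws(self) -> int | None:
        return None if self.values.ndim == 2 else self.values.shape[2]


def all_cells() -> Iterable[Cell]:
    for s in SEXES:
        for b in AGE_BANDS:
            yield (s, b)
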