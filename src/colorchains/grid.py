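"""WCS-style colour chip array: geometry, perceptual embeddings, TSV I/O.

The World Color Survey stimulus array has 330 chips: 40 equally spaced
Munsell hues at 8 lightness levels (320 chromatic chips) plus a single
achromatic column at 10 lightness levels.  Rows are indexed 0-9 from
lightest to darkest (WCS letters A-J); column 0 is achromatic, columns
1-40 are the circular hue dimension (column 40 is adjacent to column 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

N_HUE = 40
N_LIGHTNESS = 10
#: lightness rows available to chromatic chips (achromatic spans all 10)
CHROMATIC_ROWS = tuple(range(1, 9))

#: Canonical hue columns after which category boundaries preferentially
#: fall in the synthetic study.  Deliberately unevenly spaced around the
#: hue circle so that no non-zero rotation maps the set onto itself,
#: emulating the shared, non-uniform perceptual structure that anchors
#: colour-category boundaries across unrelated languages.
DEFAULT_HUE_ANCHORS = (2, 7, 16, 21, 28, 38)


class ChipTableError(ValueError):
    """Malformed chip table (bad coordinates, duplicates); carries a line number."""


@dataclass(frozen=True)
class Chip:
    """One colour chip at (lightness row, hue column)."""

    chip_id: str
    row: int
    col: int

    @property
    def is_chromatic(self) -> bool:
        return self.col >= 1

    def validate(self) -> None:
        if not 0 <= self.col <= N_HUE:
            raise ValueError(f"chip {self.chip_id}: column {self.col} outside 0-{N_HUE}")
        if self.col == 0:
            if not 0 <= self.row < N_LIGHTNESS:
                raise ValueError(f"chip {self.chip_id}: achromatic row {self.row} outside 0-9")
        elif self.row not in CHROMATIC_ROWS:
            raise ValueError(
                f"chip {self.chip_id}: chromatic chips occupy rows 1-8, got row {self.row}"
            )


def chip_id_for(row: int, col: int) -> str:
    """Canonical zero-padded identifier, e.g. row 3 col 7 -> 'R3C07'."""
    return f"R{row}C{col:02d}"


class ChipGrid:
    """Ordered, duplicate-free collection of chips; the universe all
    naming systems partition."""

    def __init__(self, chips: Iterable[Chip]):
        self.chips: tuple[Chip, ...] = tuple(chips)
        seen_ids: set[str] = set()
        seen_coords: set[tuple[int, int]] = set()
        for chip in self.chips:
            chip.validate()
            if chip.chip_id in seen_ids:
                raise ValueError(f"duplicate chip_id {chip.chip_id!r}")
            coord = (chip.row, chip.col)
            if coord in seen_coords:
                raise ValueError(f"duplicate coordinates {coord}")
            seen_ids.add(chip.chip_id)
            seen_coords.add(coord)
        self._index = {c.chip_id: i for i, c in enumerate(self.chips)}
        self._by_coord = {(c.row, c.col): c for c in self.chips}
        self.rows = np.array([c.row for c in self.chips], dtype=np.int64)
        self.cols = np.array([c.col for c in self.chips], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.chips)

    def __iter__(self) -> Iterator[Chip]:
        return iter(self.chips)

    def __contains__(self, chip_id: str) -> bool:
        return chip_id in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ChipGrid) and self.chips == other.chips

    def __hash__(self) -> int:
        return hash(self.chips)

    def index(self, chip_id: str) -> int:
        return self._index[chip_id]

    def chip_at(self, row: int, col: int) -> Chip:
        return self._by_coord[(row, col)]

    @property
    def chip_ids(self) -> tuple[str, ...]:
        return tuple(c.chip_id for c in self.chips)


def build_wcs_array() -> ChipGrid:
    """The canonical 330-chip array: 40 hues x 8 lightness + 10 achromatic."""
    chips = []
    for row in range(N_LIGHTNESS):
        for col in range(N_HUE + 1):
            if col == 0 or row in CHROMATIC_ROWS:
                chips.append(Chip(chip_id_for(row, col), row, col))
    return ChipGrid(chips)


def circular_hue_distance(c1: Chip, c2: Chip) -> int:
    """Steps around the 40-column hue circle between two chromatic chips."""
    if not (c1.is_chromatic and c2.is_chromatic):
        raise ValueError("circular hue distance is defined for chromatic chips only")
    d = abs(c1.col - c2.col)
    return min(d, N_HUE - d)


def hue_angles(anchor_strength: float = 0.0,
               anchors: Sequence[int] = DEFAULT_HUE_ANCHORS) -> np.ndarray:
    """Angular position of each hue column on the hue circle.

    Returns an array of length ``N_HUE + 1`` indexed by column (entry 0 is
    NaN: achromatic chips carry no hue).  With ``anchor_strength == 0`` the
    columns are uniformly spaced, column h at ``2*pi*h/40``.  A positive
    strength widens the angular gap immediately after each anchor column
    by a factor ``1 + anchor_strength``, creating sparse zones where an
    exemplar learner's category boundaries preferentially settle.
    """
    # gaps[j-1] = angular spacing between column j-1 and column j (column 0
    # position = origin, one full turn behind column 40); widening the gap
    # *after* anchor a means widening the spacing before column a+1.
    gaps = np.ones(N_HUE)
    for a in anchors:
        gaps[a % N_HUE] = 1.0 + anchor_strength
    angles = np.empty(N_HUE + 1)
    angles[0] = np.nan
    angles[1:] = 2.0 * np.pi * np.cumsum(gaps) / gaps.sum()
    return angles


def perceptual_embedding(chip: Chip, rho: float = 3.0) -> np.ndarray:
    """Map a chip into a 3-D perceptual space: hue circle of radius
    ``rho`` (in lightness-row units) x linear lightness axis.

    Chromatic chip (row r, col h) -> (rho cos(2 pi h/40), rho sin(2 pi h/40), r);
    achromatic -> (0, 0, r), the axis of the hue cylinder.
    """
    if chip.col == 0:
        return np.array([0.0, 0.0, float(chip.row)])
    theta = 2.0 * np.pi * chip.col / N_HUE
    return np.array([rho * np.cos(theta), rho * np.sin(theta), float(chip.row)])


def embedding_matrix(grid: ChipGrid, rho: float = 3.0,
                     anchor_strength: float = 0.0,
                     anchors: Sequence[int] = DEFAULT_HUE_ANCHORS) -> np.ndarray:
    """Embedding of every chip in the grid, shape (n_chips, 3).

    Generalizes :func:`perceptual_embedding` with optional anchor warping
    of the hue circle; at ``anchor_strength == 0`` row i equals
    ``perceptual_embedding(grid.chips[i], rho)``.
    """
    angles = hue_angles(anchor_strength, anchors)
    out = np.zeros((len(grid), 3))
    chromatic = grid.cols >= 1
    theta = angles[grid.cols[chromatic]]
    out[chromatic, 0] = rho * np.cos(theta)
    out[chromatic, 1] = rho * np.sin(theta)
    out[:, 2] = grid.rows
    return out


def write_chip_table(grid: ChipGrid, path) -> None:
    """Write a chips.tsv with header chip_id/row/col."""
    df = pd.DataFrame(
        {"chip_id": grid.chip_ids, "row": grid.rows, "col": grid.cols}
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_chip_table(path) -> ChipGrid:
    """Read a chips.tsv; raises :class:`ChipTableError` with the offending
    line number on bad coordinates or duplicates."""
    df = pd.read_csv(path, sep="\t", dtype={"chip_id": str, "row": int, "col": int})
    missing = {"chip_id", "row", "col"} - set(df.columns)
    if missing:
        raise ChipTableError(f"chip table missing columns: {sorted(missing)}")
    chips = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            chip = Chip(str(rec.chip_id), int(rec.row), int(rec.col))
            chip.validate()
        except ValueError as exc:
            raise ChipTableError(f"line {line}: {exc}") from exc
        chips.append(chip)
    try:
        return ChipGrid(chips)
    except ValueError as exc:
        raise ChipTableError(str(exc)) from exc
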