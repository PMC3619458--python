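"""Naming systems (partitions of the chip array) and their generators.

A naming system assigns one colour term to each chip (or to a subset, for
aggregate field data with unlabelled chips).  Three initial-partition
generators mirror the transmission-chain study design: contiguous hue
bands, contiguous lightness slabs, and fully random balanced partitions.
The hue-rotation operator implements the rotation-null control, and
``minority_terms`` the <5 %-of-chips minority rule used when displaying
systems.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .grid import N_HUE, N_LIGHTNESS, ChipGrid

MIN_TERMS = 2
MAX_TERMS = 6


def default_terms(k: int) -> tuple[str, ...]:
    return tuple(f"t{i}" for i in range(k))


class NamingSystem:
    """One speaker's (or one generation's) term assignment over a grid.

    ``labels`` maps chip_id -> term; chips absent from the mapping are
    unlabelled.  Treat instances as immutable once built: integer term
    codes are cached for the metric computations.
    """

    def __init__(self, grid: ChipGrid, labels: Mapping[str, str],
                 term_inventory: Optional[Sequence[str]] = None):
        self.grid = grid
        self.labels = dict(labels)
        for chip_id in self.labels:
            if chip_id not in grid:
                raise ValueError(f"labelled chip {chip_id!r} not in grid")
        used = set(self.labels.values())
        if term_inventory is None:
            term_inventory = sorted(used)
        self.term_inventory: tuple[str, ...] = tuple(dict.fromkeys(term_inventory))
        stray = used - set(self.term_inventory)
        if stray:
            raise ValueError(f"labels use terms outside the inventory: {sorted(stray)}")
        self._codes: Optional[np.ndarray] = None

    @property
    def is_complete(self) -> bool:
        return len(self.labels) == len(self.grid)

    @property
    def n_labelled(self) -> int:
        return len(self.labels)

    def used_terms(self) -> set[str]:
        return set(self.labels.values())

    def term_counts(self) -> Counter:
        return Counter(self.labels.values())

    def codes(self) -> np.ndarray:
        """Term index per chip in grid order; -1 marks unlabelled chips."""
        if self._codes is None:
            term_idx = {t: i for i, t in enumerate(self.term_inventory)}
            codes = np.full(len(self.grid), -1, dtype=np.int64)
            for chip_id, term in self.labels.items():
                codes[self.grid.index(chip_id)] = term_idx[term]
            self._codes = codes
        return self._codes

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, NamingSystem) and self.grid == other.grid
                and self.labels == other.labels)

    def __repr__(self) -> str:
        return (f"NamingSystem({self.n_labelled}/{len(self.grid)} chips, "
                f"{len(self.used_terms())} terms)")


def _check_k(k: int) -> None:
    if not MIN_TERMS <= k <= MAX_TERMS:
        raise ValueError(f"term count must be in [{MIN_TERMS}, {MAX_TERMS}], got {k}")


def balanced_sizes(n: int, k: int) -> list[int]:
    """Split n items into k contiguous groups differing by at most one,
    remainder allotted to the leading groups."""
    base, rem = divmod(n, k)
    return [base + 1 if i < rem else base for i in range(k)]


def hue_partition(grid: ChipGrid, k: int, seed: int = 0) -> NamingSystem:
    """Vertical partition: k contiguous hue bands of near-equal width;
    the achromatic column joins one band chosen uniformly at random."""
    _check_k(k)
    terms = default_terms(k)
    sizes = balanced_sizes(N_HUE, k)
    band_of_col = {}
    col = 1
    for band, size in enumerate(sizes):
        for _ in range(size):
            band_of_col[col] = band
            col += 1
    rng = np.random.default_rng(seed)
    achromatic_band = int(rng.integers(k))
    labels = {}
    for chip in grid:
        band = achromatic_band if chip.col == 0 else band_of_col[chip.col]
        labels[chip.chip_id] = terms[band]
    return NamingSystem(grid, labels, terms)


def lightness_partition(grid: ChipGrid, k: int) -> NamingSystem:
    """Horizontal partition: lightness rows split into k contiguous
    near-equal groups (deterministic; largest groups lightest)."""
    _check_k(k)
    terms = default_terms(k)
    sizes = balanced_sizes(N_LIGHTNESS, k)
    group_of_row = {}
    row = 0
    for group, size in enumerate(sizes):
        for _ in range(size):
            group_of_row[row] = group
            row += 1
    labels = {chip.chip_id: terms[group_of_row[chip.row]] for chip in grid}
    return NamingSystem(grid, labels, terms)


def random_partition(grid: ChipGrid, k: int, seed: int = 0) -> NamingSystem:
    """Uniformly random partition with per-term chip counts balanced to
    within one (exactly equal whenever k divides the grid size)."""
    _check_k(k)
    terms = default_terms(k)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(grid))
    sizes = balanced_sizes(len(grid), k)
    labels = {}
    start = 0
    for term, size in zip(terms, sizes):
        for idx in order[start:start + size]:
            labels[grid.chips[idx].chip_id] = term
        start += size
    return NamingSystem(grid, labels, terms)


def rotate_hue(ns: NamingSystem, steps: int) -> NamingSystem:
    """Rotate a complete system ``steps`` columns rightward along the hue
    circle: the chip at (r, h) takes the label of (r, h - steps), modulo
    40.  Achromatic chips have no hue and are left unchanged.  Term
    frequencies over chromatic chips are preserved."""
    if not ns.is_complete:
        raise ValueError("rotation requires a complete labelling")
    steps = steps % N_HUE
    labels = {}
    for chip in ns.grid:
        if chip.col == 0:
            labels[chip.chip_id] = ns.labels[chip.chip_id]
        else:
            src_col = ((chip.col - 1 - steps) % N_HUE) + 1
            src = ns.grid.chip_at(chip.row, src_col)
            labels[chip.chip_id] = ns.labels[src.chip_id]
    return NamingSystem(ns.grid, labels, ns.term_inventory)


def minority_terms(ns: NamingSystem, threshold: float = 0.05) -> set[str]:
    """Terms labelling strictly fewer than ``threshold`` of all chips."""
    if not ns.is_complete:
        raise ValueError("minority rule requires a complete labelling")
    cutoff = threshold * len(ns.grid)
    return {term for term, count in ns.term_counts().items() if count < cutoff}


# --- naming.tsv I/O -------------------------------------------------------

NAMING_COLUMNS = ("language_id", "speaker_id", "chip_id", "term")


def write_naming_table(path, systems: Iterable[tuple[str, str, NamingSystem]]) -> None:
    """Write (language_id, speaker_id, system) triples as a naming.tsv.

    Unlabelled chips are simply absent from the file.
    """
    rows = []
    for language_id, speaker_id, ns in systems:
        for chip in ns.grid:  # grid order keeps output deterministic
            term = ns.labels.get(chip.chip_id)
            if term is not None:
                rows.append((language_id, speaker_id, chip.chip_id, term))
    df = pd.DataFrame(rows, columns=NAMING_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_naming_table(path, grid: ChipGrid) -> dict[str, dict[str, NamingSystem]]:
    """Read a naming.tsv into language -> speaker -> NamingSystem."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(NAMING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"naming table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, NamingSystem]] = {}
    for (lang, spk), sub in df.groupby(["language_id", "speaker_id"], sort=True):
        labels = dict(zip(sub["chip_id"], sub["term"]))
        out.setdefault(str(lang), {})[str(spk)] = NamingSystem(grid, labels)
    return out


def write_single_system(path, ns: NamingSystem,
                        language_id: str = "lang0", speaker_id: str = "spk0") -> None:
    write_naming_table(path, [(language_id, speaker_id, ns)])
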