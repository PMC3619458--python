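"""Variation of information between naming systems, and the corpus
averaging procedures used to compare transmission chains against a
multi-language reference corpus.

For two clusterings C and C' of the same chips,

    VI(C, C') = H(C) + H(C') - 2 I(C, C')

with entropy H and mutual information I in nats.  VI is a metric on
partitions (up to term renaming) bounded by ln(n).  Systems with
unlabelled chips are compared over the intersection of labelled chips.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .grid import ChipGrid
from .partitions import NamingSystem, read_naming_table, write_naming_table

LanguageFilter = Callable[[str, Mapping[str, NamingSystem]], bool]


class SpeakerCorpus:
    """languages -> speakers -> NamingSystem, all over one shared grid."""

    def __init__(self, languages: Mapping[str, Mapping[str, NamingSystem]]):
        if not languages:
            raise ValueError("corpus must contain at least one language")
        self.languages: dict[str, dict[str, NamingSystem]] = {
            lang: dict(speakers) for lang, speakers in languages.items()
        }
        first = None
        for lang, speakers in self.languages.items():
            if not speakers:
                raise ValueError(f"language {lang!r} has no speakers")
            for ns in speakers.values():
                if first is None:
                    first = ns.grid
                elif ns.grid != first:
                    raise ValueError("all systems in a corpus must share one grid")
        assert first is not None
        self.grid = first

    @property
    def language_ids(self) -> list[str]:
        return sorted(self.languages)

    @property
    def n_languages(self) -> int:
        return len(self.languages)

    @property
    def n_speakers(self) -> int:
        return sum(len(s) for s in self.languages.values())

    def systems(self) -> Iterable[tuple[str, str, NamingSystem]]:
        for lang in self.language_ids:
            for spk in sorted(self.languages[lang]):
                yield lang, spk, self.languages[lang][spk]

    @classmethod
    def from_tsv(cls, path, grid: ChipGrid) -> "SpeakerCorpus":
        return cls(read_naming_table(path, grid))

    def to_tsv(self, path) -> None:
        write_naming_table(path, self.systems())


# --- core information quantities -----------------------------------------


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def entropy(ns: NamingSystem) -> float:
    """Partition entropy H(C) = -sum_k P(k) ln P(k), in nats, over the
    labelled chips; 0 ln 0 = 0."""
    codes = ns.codes()
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise ValueError("entropy of an empty labelling is undefined")
    return _entropy_from_counts(np.bincount(codes))


def _common_codes(a: NamingSystem, b: NamingSystem) -> tuple[np.ndarray, np.ndarray]:
    if a.grid != b.grid:
        raise ValueError("systems must partition the same grid")
    ca, cb = a.codes(), b.codes()
    mask = (ca >= 0) & (cb >= 0)
    if not mask.any():
        raise ValueError("no commonly labelled chips")
    return ca[mask], cb[mask]


def _pair_info(ca: np.ndarray, cb: np.ndarray) -> tuple[float, float, float]:
    """(H(a), H(b), I(a,b)) from aligned code arrays (no -1 entries)."""
    na = int(ca.max()) + 1
    nb = int(cb.max()) + 1
    joint = np.bincount(ca * nb + cb, minlength=na * nb).astype(np.float64)
    n = joint.sum()
    row = joint.reshape(na, nb).sum(axis=1)
    colm = joint.reshape(na, nb).sum(axis=0)
    h_a = _entropy_from_counts(row)
    h_b = _entropy_from_counts(colm)
    nz = joint > 0
    pij = joint[nz] / n
    outer = (row[:, None] * colm[None, :]).reshape(-1)[nz] / (n * n)
    mi = float((pij * np.log(pij / outer)).sum())
    return h_a, h_b, mi


def mutual_information(a: NamingSystem, b: NamingSystem) -> float:
    """I(C, C') in nats over the commonly labelled chips."""
    ca, cb = _common_codes(a, b)
    return _pair_info(ca, cb)[2]


def variation_of_information(a: NamingSystem, b: NamingSystem) -> float:
    """VI(C, C') = H(C) + H(C') - 2 I(C, C'), in nats, over the commonly
    labelled chips.  Zero iff the partitions agree up to term renaming."""
    ca, cb = _common_codes(a, b)
    h_a, h_b, mi = _pair_info(ca, cb)
    return max(0.0, h_a + h_b - 2.0 * mi)


def _vi_codes(ca: np.ndarray, cb: np.ndarray) -> float:
    mask = (ca >= 0) & (cb >= 0)
    h_a, h_b, mi = _pair_info(ca[mask], cb[mask])
    return max(0.0, h_a + h_b - 2.0 * mi)


# --- corpus averaging ------------------------------------------------------


def mean_vi_to_corpus(ns: NamingSystem, corpus: SpeakerCorpus,
                      language_filter: Optional[LanguageFilter] = None) -> float:
    """Two-stage mean VI from one system to a corpus: average over each
    language's speakers first, then (unweighted) over languages, so
    well-sampled languages do not dominate."""
    codes = ns.codes()
    language_means = []
    for lang in corpus.language_ids:
        speakers = corpus.languages[lang]
        if language_filter is not None and not language_filter(lang, speakers):
            continue
        vis = [_vi_codes(codes, s.codes()) for s in speakers.values()]
        language_means.append(float(np.mean(vis)))
    if not language_means:
        raise ValueError("no languages remain after filtering")
    return float(np.mean(language_means))


def corpus_pairwise_vi(corpus: SpeakerCorpus) -> float:
    """Mean between-language VI of a corpus: for every unordered pair of
    distinct languages average VI over all cross-language speaker pairs,
    then average (unweighted) over language pairs."""
    langs = corpus.language_ids
    if len(langs) < 2:
        raise ValueError("pairwise VI requires at least two languages")
    coded = {
        lang: [s.codes() for _, s in sorted(corpus.languages[lang].items())]
        for lang in langs
    }
    pair_means = []
    for i, la in enumerate(langs):
        for lb in langs[i + 1:]:
            vis = [_vi_codes(ca, cb) for ca in coded[la] for cb in coded[lb]]
            pair_means.append(float(np.mean(vis)))
    return float(np.mean(pair_means))


def language_cross_vis(corpus: SpeakerCorpus) -> dict[str, float]:
    """Per-language mean VI to the rest of the corpus: for language L,
    the unweighted mean over other languages of the mean cross-speaker
    VI.  One value per language (the corpus-side sample in two-sample
    comparisons against chain finals)."""
    langs = corpus.language_ids
    if len(langs) < 2:
        raise ValueError("cross-language VI requires at least two languages")
    coded = {
        lang: [s.codes() for _, s in sorted(corpus.languages[lang].items())]
        for lang in langs
    }
    out = {}
    for la in langs:
        others = []
        for lb in langs:
            if lb == la:
                continue
            vis = [_vi_codes(ca, cb) for ca in coded[la] for cb in coded[lb]]
            others.append(float(np.mean(vis)))
        out[la] = float(np.mean(others))
    return out


def speaker_internal_vis(corpus: SpeakerCorpus) -> list[float]:
    """Per-speaker mean VI to every other speaker in the corpus,
    regardless of language (used when the reference is a single group of
    speakers, e.g. one language's control data)."""
    coded = [s.codes() for _, _, s in corpus.systems()]
    if len(coded) < 2:
        raise ValueError("need at least two speakers")
    out = []
    for i, ci in enumerate(coded):
        vis = [_vi_codes(ci, cj) for j, cj in enumerate(coded) if j != i]
        out.append(float(np.mean(vis)))
    return out


def closest_language(chain, corpus: SpeakerCorpus,
                     iteration_window: tuple[int, int] = (4, 13)) -> str:
    """The corpus language with the lowest VI to a chain, averaged over
    the iterations in ``iteration_window`` (inclusive) and over that
    language's speakers; ties break lexicographically.

    ``chain`` may be a ChainRecord or any sequence of NamingSystems
    indexed by iteration (0 = initial partition).
    """
    generations = getattr(chain, "generations", chain)
    lo, hi = iteration_window
    if lo < 0 or hi >= len(generations):
        raise ValueError(
            f"window {iteration_window} exceeds chain length {len(generations) - 1}"
        )
    window_codes = [generations[g].codes() for g in range(lo, hi + 1)]
    best: Optional[tuple[float, str]] = None
    for lang in corpus.language_ids:
        speaker_codes = [s.codes() for s in corpus.languages[lang].values()]
        vis = [_vi_codes(g, s) for g in window_codes for s in speaker_codes]
        mean = float(np.mean(vis))
        if best is None or (mean, lang) < best:
            best = (mean, lang)
    assert best is not None
    return best[1]


def same_term_count_filter(k: int) -> LanguageFilter:
    """Language filter keeping languages whose speakers use exactly k terms
    (majority vote over speakers), for same-size comparisons."""

    def _filter(lang: str, speakers: Mapping[str, NamingSystem]) -> bool:
        counts = [len(s.used_terms()) for s in speakers.values()]
        return int(np.median(counts)) == k

    return _filter
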