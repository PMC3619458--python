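"""Iterated-learning chain simulation and synthetic reference corpora.

Each chain transmits a colour-naming system through a sequence of
simulated learners: generation g is trained on 6*k labelled chips
sampled from generation g-1's system (k = term count) and must then
label all chips.  The bundled exemplar learner is an explicit stand-in
for human participants: it labels chips by similarity to the training
exemplars in a cylindrical perceptual space, optionally warped so that
category boundaries are attracted to a fixed set of canonical hue
columns.  The corpus generator emulates a survey-style multi-language
reference corpus whose languages share those same boundary anchors.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .grid import DEFAULT_HUE_ANCHORS, N_HUE, ChipGrid, build_wcs_array, embedding_matrix
from .partitions import (NamingSystem, default_terms, hue_partition,
                         lightness_partition, random_partition)
from .vi import SpeakerCorpus

#: training examples shown per term in the transmitted language
EXAMPLES_PER_TERM = 6
DEFAULT_GENERATIONS = 13

INITIAL_KINDS = ("random", "hue", "lightness")


def derived_seed(master: int, *tags) -> np.random.SeedSequence:
    """A named, reproducible child seed stream.

    Tags (chain ids, generation numbers, stage names) are folded into the
    seed-sequence key so every chain/generation draws from an independent
    stream of one master seed.
    """
    import zlib

    key = [int(master) & 0x7FFFFFFF]
    for tag in tags:
        key.append(zlib.crc32(str(tag).encode()) & 0x7FFFFFFF)
    return np.random.SeedSequence(key)


def rng_for(master: int, *tags) -> np.random.Generator:
    return np.random.default_rng(derived_seed(master, *tags))


class TrainingExample(NamedTuple):
    chip_id: str
    term: str


class Learner(Protocol):
    """Contract for generation-level learners: consume labelled examples,
    return a complete naming system using only the given inventory."""

    def learn(self, examples: Sequence[TrainingExample], grid: ChipGrid,
              term_inventory: Sequence[str], seed) -> NamingSystem: ...


def sample_training_set(ns: NamingSystem, k: int, seed) -> list[TrainingExample]:
    """6*k distinct chips drawn uniformly without replacement from the
    grid, each paired with its label in ``ns``."""
    if not ns.is_complete:
        raise ValueError("training sets are sampled from complete systems")
    n_examples = EXAMPLES_PER_TERM * k
    if n_examples > len(ns.grid):
        raise ValueError(f"cannot sample {n_examples} distinct chips from "
                         f"{len(ns.grid)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ns.grid), size=n_examples, replace=False)
    return [TrainingExample(ns.grid.chips[i].chip_id, ns.labels[ns.grid.chips[i].chip_id])
            for i in idx]


@dataclass
class ExemplarLearner:
    """Similarity-based stand-in for a human participant.

    Each chip is labelled by sampling a term with probability
    proportional to sum over that term's exemplars of exp(-d / tau),
    where d is Euclidean distance in the perceptual embedding.  tau -> 0
    recovers deterministic nearest-exemplar labelling (ties resolved
    uniformly at random); large tau approaches uniform guessing.
    ``anchor_strength`` > 0 warps hue spacing so boundaries drift toward
    the canonical anchor columns; 0 gives the uniform hue circle.
    """

    tau: float = 0.3
    rho: float = 3.0
    anchor_strength: float = 3.0
    anchors: tuple[int, ...] = DEFAULT_HUE_ANCHORS

    def params(self) -> dict:
        return {"learner": "exemplar", "tau": self.tau, "rho": self.rho,
                "anchor_strength": self.anchor_strength,
                "anchors": list(self.anchors)}

    def learn(self, examples: Sequence[TrainingExample], grid: ChipGrid,
              term_inventory: Sequence[str], seed) -> NamingSystem:
        if not examples:
            raise ValueError("learner requires at least one training example")
        rng = np.random.default_rng(seed)
        emb = embedding_matrix(grid, self.rho, self.anchor_strength, self.anchors)
        ex_idx = np.array([grid.index(e.chip_id) for e in examples])
        observed_terms = sorted(set(e.term for e in examples),
                                key=list(term_inventory).index)
        term_of_example = np.array([observed_terms.index(e.term) for e in examples])
        # (n_chips, n_examples) distances in embedding space
        diff = emb[:, None, :] - emb[ex_idx][None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        if self.tau <= 0.0:
            choice = self._nearest(dist, term_of_example, len(observed_terms), rng)
        else:
            dmin = dist.min(axis=1, keepdims=True)
            w = np.exp(-(dist - dmin) / self.tau)
            scores = np.zeros((len(grid), len(observed_terms)))
            for t in range(len(observed_terms)):
                scores[:, t] = w[:, term_of_example == t].sum(axis=1)
            probs = scores / scores.sum(axis=1, keepdims=True)
            cum = np.cumsum(probs, axis=1)
            u = rng.random(len(grid))
            choice = (cum < u[:, None]).sum(axis=1)
        labels = {chip.chip_id: observed_terms[choice[i]]
                  for i, chip in enumerate(grid.chips)}
        return NamingSystem(grid, labels, term_inventory)

    @staticmethod
    def _nearest(dist: np.ndarray, term_of_example: np.ndarray,
                 n_terms: int, rng: np.random.Generator) -> np.ndarray:
        dmin = dist.min(axis=1, keepdims=True)
        tied = dist <= dmin + 1e-12
        choice = np.empty(dist.shape[0], dtype=np.int64)
        for i in range(dist.shape[0]):
            candidates = np.unique(term_of_example[tied[i]])
            choice[i] = candidates[0] if candidates.size == 1 else rng.choice(candidates)
        return choice


@dataclass
class ChainConfig:
    chain_id: str
    k: int
    initial_kind: str
    seed: int


@dataclass
class ChainRecord:
    """One transmission chain: generation 0 is the initial partition,
    generations 1..G are learner outputs; training_sets[g-1] is the 6*k
    example set that trained generation g."""

    chain_id: str
    k: int
    initial_kind: str
    generations: list[NamingSystem]
    training_sets: list[list[TrainingExample]] = field(default_factory=list)
    seed: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.generations) - 1

    @property
    def final(self) -> NamingSystem:
        return self.generations[-1]


def run_chain(initial: NamingSystem, learner: Learner,
              generations: int = DEFAULT_GENERATIONS, seed: int = 0,
              chain_id: str = "chain", initial_kind: str = "custom",
              k: Optional[int] = None) -> ChainRecord:
    """Iterate sample-then-learn for ``generations`` steps from a complete
    initial system, recording every intermediate system and training set."""
    if not initial.is_complete:
        raise ValueError("initial partition must label every chip")
    if generations < 1:
        raise ValueError("need at least one generation")
    if k is None:
        k = len(initial.term_inventory)
    record = ChainRecord(chain_id, k, initial_kind, [initial], [], seed)
    current = initial
    for g in range(1, generations + 1):
        sample_rng = rng_for(seed, chain_id, "sample", g)
        examples = sample_training_set(current, k, sample_rng)
        learn_rng = rng_for(seed, chain_id, "learn", g)
        current = learner.learn(examples, initial.grid, initial.term_inventory,
                                learn_rng)
        record.training_sets.append(examples)
        record.generations.append(current)
    return record


def build_experiment_design(seed: int = 0,
                            k_range: tuple[int, int] = (2, 6),
                            n_random_per_k: int = 4) -> list[ChainConfig]:
    """The 30-chain study design: for each term count k in 2..6, four
    chains from random initial partitions plus one hue and one lightness
    chain, each with its own derived seed."""
    configs = []
    for k in range(k_range[0], k_range[1] + 1):
        for r in range(n_random_per_k):
            cid = f"random-k{k}-{r}"
            configs.append(ChainConfig(cid, k, "random",
                                       int(rng_for(seed, cid).integers(2 ** 31))))
        for kind in ("hue", "lightness"):
            cid = f"{kind}-k{k}"
            configs.append(ChainConfig(cid, k, kind,
                                       int(rng_for(seed, cid).integers(2 ** 31))))
    return configs


def realize_initial(config: ChainConfig, grid: ChipGrid) -> NamingSystem:
    if config.initial_kind == "random":
        return random_partition(grid, config.k, config.seed)
    if config.initial_kind == "hue":
        return hue_partition(grid, config.k, config.seed)
    if config.initial_kind == "lightness":
        return lightness_partition(grid, config.k)
    raise ValueError(f"unknown initial kind {config.initial_kind!r}")


def run_design(design: Sequence[ChainConfig], grid: ChipGrid, learner: Learner,
               generations: int = DEFAULT_GENERATIONS) -> list[ChainRecord]:
    return [
        run_chain(realize_initial(cfg, grid), learner, generations,
                  seed=cfg.seed, chain_id=cfg.chain_id,
                  initial_kind=cfg.initial_kind, k=cfg.k)
        for cfg in design
    ]


# --- synthetic reference corpus -------------------------------------------


def _band_template(grid: ChipGrid, boundaries: Sequence[int],
                   terms: Sequence[str], achromatic_band: int,
                   stripe_rows: Optional[set[int]] = None,
                   stripe_term: Optional[str] = None) -> dict[str, str]:
    """Contiguous cyclic hue bands delimited by 'after column b'
    boundaries, with an optional lightness stripe overriding them."""
    bounds = sorted(boundaries)

    def band_of(col: int) -> int:
        n_before = sum(1 for b in bounds if b < col)
        return n_before % len(bounds)  # cols <= first bound wrap into band 0

    labels = {}
    for chip in grid:
        if stripe_rows is not None and chip.row in stripe_rows:
            labels[chip.chip_id] = stripe_term
            continue
        if chip.col == 0:
            labels[chip.chip_id] = terms[achromatic_band]
        else:
            labels[chip.chip_id] = terms[band_of(chip.col)]
    return labels


def _neighbour_indices(grid: ChipGrid) -> list[list[int]]:
    out = []
    for chip in grid:
        nbrs = []
        for dr in (-1, 1):
            coord = (chip.row + dr, chip.col)
            if coord in grid._by_coord:
                nbrs.append(grid.index(grid._by_coord[coord].chip_id))
        if chip.col >= 1:
            for dc in (-1, 1):
                col = ((chip.col - 1 + dc) % N_HUE) + 1
                coord = (chip.row, col)
                if coord in grid._by_coord:
                    nbrs.append(grid.index(grid._by_coord[coord].chip_id))
        out.append(nbrs)
    return out


def generate_synthetic_corpus(n_languages: int = 110,
                              k_range: tuple[int, int] = (2, 6),
                              speakers_per_language: int = 10,
                              noise_eps: float = 0.05,
                              seed: int = 0,
                              grid: Optional[ChipGrid] = None,
                              anchors: Sequence[int] = DEFAULT_HUE_ANCHORS,
                              boundary_jitter: int = 1,
                              lightness_split_prob: float = 0.3) -> SpeakerCorpus:
    """A survey-like reference corpus of 2-6-term naming systems.

    Each language draws a term count k and a template: contiguous hue
    bands whose boundaries sit at a k-subset of the shared anchor
    columns (jittered by up to ``boundary_jitter`` columns per
    language), optionally sacrificing one term to a light or dark
    lightness stripe.  Each speaker then flips every chip's label to a
    neighbouring category's label independently with probability
    ``noise_eps``, so within-language variation is boundary noise.
    """
    if not 0.0 <= noise_eps < 0.5:
        raise ValueError("noise_eps must lie in [0, 0.5)")
    if n_languages < 1 or speakers_per_language < 1:
        raise ValueError("need at least one language and one speaker")
    if k_range[1] > len(anchors):
        raise ValueError("need at least as many anchors as the largest term count")
    if grid is None:
        grid = build_wcs_array()
    neighbours = _neighbour_indices(grid)
    languages: dict[str, dict[str, NamingSystem]] = {}
    for li in range(n_languages):
        lrng = rng_for(seed, "language", li)
        k = int(lrng.integers(k_range[0], k_range[1] + 1))
        terms = default_terms(k)
        stripe_rows: Optional[set[int]] = None
        stripe_term: Optional[str] = None
        n_bands = k
        if k >= 2 and lrng.random() < lightness_split_prob:
            stripe_term = terms[-1]
            stripe_rows = {0, 1} if lrng.random() < 0.5 else {8, 9}
            n_bands = k - 1
        if n_bands >= 2:
            chosen = sorted(lrng.choice(len(anchors), size=n_bands, replace=False))
            boundaries = []
            for ci in chosen:
                b = anchors[ci]
                if boundary_jitter:
                    b += int(lrng.integers(-boundary_jitter, boundary_jitter + 1))
                boundaries.append(((b - 1) % N_HUE) + 1)
            band_terms = terms[:n_bands]
            achromatic_band = int(lrng.integers(n_bands))
        else:  # one hue band: everything chromatic shares a term
            boundaries = [int(anchors[0])]
            band_terms = terms[:1]
            achromatic_band = 0
        template = _band_template(grid, boundaries, band_terms, achromatic_band,
                                  stripe_rows, stripe_term)
        template_codes = [template[c.chip_id] for c in grid.chips]
        speakers = {}
        for si in range(speakers_per_language):
            srng = rng_for(seed, "language", li, "speaker", si)
            labels = list(template_codes)
            flips = np.flatnonzero(srng.random(len(grid)) < noise_eps)
            for i in flips:
                options = [labels[j] for j in neighbours[i] if labels[j] != labels[i]]
                if options:
                    labels[i] = options[int(srng.integers(len(options)))]
            speakers[f"spk{si:02d}"] = NamingSystem(
                grid, dict(zip(grid.chip_ids, labels)), terms)
        languages[f"lang{li:03d}"] = speakers
    return SpeakerCorpus(languages)


# --- chain serialization ---------------------------------------------------


def write_chains(records: Sequence[ChainRecord], out_dir,
                 learner_params: Optional[dict] = None) -> None:
    """Serialize chains as chains.tsv + training.tsv + manifest.json."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        for it, ns in enumerate(rec.generations):
            for chip in ns.grid:
                term = ns.labels.get(chip.chip_id)
                if term is not None:
                    rows.append((rec.chain_id, it, chip.chip_id, term))
    pd.DataFrame(rows, columns=["chain_id", "iteration", "chip_id", "term"]).to_csv(
        os.path.join(out_dir, "chains.tsv"), sep="\t", index=False,
        lineterminator="\n")
    trows = []
    for rec in records:
        for g, examples in enumerate(rec.training_sets, start=1):
            for ex in examples:
                trows.append((rec.chain_id, g, ex.chip_id, ex.term))
    pd.DataFrame(trows, columns=["chain_id", "iteration", "chip_id", "term"]).to_csv(
        os.path.join(out_dir, "training.tsv"), sep="\t", index=False,
        lineterminator="\n")
    manifest = {
        "learner": learner_params or {},
        "chains": [
            {"chain_id": r.chain_id, "k": r.k, "initial_kind": r.initial_kind,
             "seed": r.seed, "generations": r.n_generations,
             "terms": list(r.generations[0].term_inventory)}
            for r in records
        ],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_chains(out_dir, grid: ChipGrid) -> list[ChainRecord]:
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    systems = pd.read_csv(os.path.join(out_dir, "chains.tsv"), sep="\t",
                          dtype={"chain_id": str, "iteration": int,
                                 "chip_id": str, "term": str})
    training = pd.read_csv(os.path.join(out_dir, "training.tsv"), sep="\t",
                           dtype={"chain_id": str, "iteration": int,
                                  "chip_id": str, "term": str})
    records = []
    for meta in manifest["chains"]:
        cid = meta["chain_id"]
        terms = tuple(meta["terms"])
        gens = []
        sub = systems[systems["chain_id"] == cid]
        for it in sorted(sub["iteration"].unique()):
            part = sub[sub["iteration"] == it]
            gens.append(NamingSystem(grid, dict(zip(part["chip_id"], part["term"])),
                                     terms))
        tsub = training[training["chain_id"] == cid]
        tsets = []
        for it in sorted(tsub["iteration"].unique()):
            part = tsub[tsub["iteration"] == it]
            tsets.append([TrainingExample(c, t)
                          for c, t in zip(part["chip_id"], part["term"])])
        records.append(ChainRecord(cid, int(meta["k"]), meta["initial_kind"],
                                   gens, tsets, int(meta["seed"])))
    return records
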