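"""Study orchestration: convergence curves, the rotation-null control,
and second-corpus comparisons, with TSV/JSON/plot output.

Three analyses mirror the transmission-chain study:

* convergence — per-iteration mean VI between chains and a reference
  corpus, against the corpus's own between-language VI baseline, with a
  paired t-test on initial vs final systems and a Spearman trend;
* rotation null — mean VI of the final systems after cyclic shifts of
  0..20 columns along the hue dimension, with paired tests of the
  unrotated fit against landmark offsets;
* second corpus — two-sample t-test asking whether chain finals are as
  close to a corpus as that corpus's systems are to each other.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import chains as chains_mod
from .chains import (ChainRecord, ExemplarLearner, build_experiment_design,
                     generate_synthetic_corpus, run_design, write_chains)
from .grid import DEFAULT_HUE_ANCHORS, build_wcs_array
from .partitions import NamingSystem, rotate_hue
from .vi import (SpeakerCorpus, closest_language, corpus_pairwise_vi,
                 language_cross_vis, mean_vi_to_corpus, speaker_internal_vis)

log = logging.getLogger("colorchains")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p}


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired t-test; df = n - 1."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical samples: no difference at all
            return TTestResult(0.0, a.size - 1, 1.0)
        raise ValueError("degenerate paired sample: zero variance of differences")
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), a.size - 1, float(res.pvalue))


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 welch: bool = False) -> TTestResult:
    """Two-sample t-test; pooled variance by default (df = n1 + n2 - 2),
    Welch's correction optional."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TTestResult(0.0, a.size + b.size - 2, 1.0)
        raise ValueError("degenerate zero-variance samples")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else a.size + b.size - 2
    return TTestResult(float(res.statistic), int(round(df)), float(res.pvalue))


@dataclass
class ConvergenceCurve:
    iterations: np.ndarray            # 0..G (0 = initial partitions)
    mean_vi: np.ndarray               # mean over chains per iteration
    sd_vi: np.ndarray
    per_chain: np.ndarray             # (n_chains, G + 1)
    chain_ids: list[str]
    baseline: Optional[float]         # between-language VI of the reference
    first_vs_last: TTestResult
    spearman_rho: float
    spearman_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": self.iterations,
                             "mean_vi": self.mean_vi, "sd_vi": self.sd_vi})


def convergence_analysis(chain_records: Sequence[ChainRecord],
                         reference: SpeakerCorpus,
                         compute_baseline: bool = True) -> ConvergenceCurve:
    """Per-iteration mean VI between chains and a reference corpus."""
    if not chain_records:
        raise ValueError("no chains supplied")
    lengths = {len(r.generations) for r in chain_records}
    if len(lengths) != 1:
        raise ValueError("chains must share a generation count")
    per_chain = np.array([
        [mean_vi_to_corpus(ns, reference) for ns in rec.generations]
        for rec in chain_records
    ])
    mean_vi = per_chain.mean(axis=0)
    iterations = np.arange(per_chain.shape[1])
    if len(chain_records) >= 2:
        test = paired_t(per_chain[:, 0], per_chain[:, -1])
    else:
        test = TTestResult(float("nan"), 0, float("nan"))
    if np.ptp(mean_vi) == 0:  # flat curve: no trend by definition
        rho, rho_p = 0.0, 1.0
    else:
        rho, rho_p = stats.spearmanr(iterations, mean_vi)
    baseline = corpus_pairwise_vi(reference) if compute_baseline else None
    return ConvergenceCurve(iterations, mean_vi, per_chain.std(axis=0, ddof=0),
                            per_chain, [r.chain_id for r in chain_records],
                            baseline, test, float(rho), float(rho_p))


def chain_vi_table(chain_records: Sequence[ChainRecord],
                   reference: SpeakerCorpus) -> pd.DataFrame:
    """Long-format chain_id / iteration / mean_vi table."""
    rows = []
    for rec in chain_records:
        for it, ns in enumerate(rec.generations):
            rows.append((rec.chain_id, it, mean_vi_to_corpus(ns, reference)))
    return pd.DataFrame(rows, columns=["chain_id", "iteration", "mean_vi"])


@dataclass
class RotationProfile:
    offsets: np.ndarray               # 0..max_steps
    mean_vi: np.ndarray               # mean over finals per offset
    per_final: np.ndarray             # (n_finals, max_steps + 1)
    landmark_tests: dict[int, TTestResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_vi": self.mean_vi})


def rotation_analysis(finals: Sequence[NamingSystem], reference: SpeakerCorpus,
                      max_steps: int = 20,
                      landmark_offsets: Sequence[int] = (5, 15, 20)
                      ) -> RotationProfile:
    """Mean VI to the reference for each hue rotation 0..max_steps of the
    final systems, plus paired tests of offset 0 against landmark
    offsets (quarter / three-quarter / maximum of the tested range)."""
    if not finals:
        raise ValueError("no final systems supplied")
    offsets = np.arange(max_steps + 1)
    per_final = np.array([
        [mean_vi_to_corpus(rotate_hue(ns, int(s)), reference) for s in offsets]
        for ns in finals
    ])
    tests = {}
    if len(finals) >= 2:
        for s in landmark_offsets:
            if 0 < s <= max_steps:
                tests[int(s)] = paired_t(per_final[:, 0], per_final[:, s])
    return RotationProfile(offsets, per_final.mean(axis=0), per_final, tests)


@dataclass
class CorpusComparison:
    """Chain finals vs a corpus's own internal similarity."""

    final_vis: list[float]            # per chain: mean VI of final system
    internal_vis: list[float]         # per language (or speaker) internal VI
    test: TTestResult

    def as_dict(self) -> dict:
        return {"mean_final_vi": float(np.mean(self.final_vis)),
                "mean_internal_vi": float(np.mean(self.internal_vis)),
                "n_finals": len(self.final_vis),
                "n_internal": len(self.internal_vis),
                **{f"test_{k}": v for k, v in self.test.as_dict().items()}}


def second_corpus_comparison(chain_records: Sequence[ChainRecord],
                             corpus: SpeakerCorpus) -> CorpusComparison:
    """Two-sample t (pooled df = n1 + n2 - 2) between the chains' final
    VI-to-corpus values and the corpus's internal values: one per
    language when the corpus is multi-language, one per speaker when it
    is a single group of speakers."""
    final_vis = [mean_vi_to_corpus(r.final, corpus) for r in chain_records]
    if corpus.n_languages >= 2:
        internal = list(language_cross_vis(corpus).values())
    else:
        internal = speaker_internal_vis(corpus)
    return CorpusComparison(final_vis, internal, two_sample_t(final_vis, internal))


# --- full study ------------------------------------------------------------

#: control-corpus anchors: a deliberately different uneven boundary set
CONTROL_HUE_ANCHORS = (5, 12, 18, 26, 34, 40)


@dataclass
class StudyConfig:
    """Everything needed to reproduce a full synthetic study."""

    n_languages: int = 110
    speakers_per_language: int = 10
    noise_eps: float = 0.05
    k_range: tuple[int, int] = (2, 6)
    lightness_split_prob: float = 0.3
    boundary_jitter: int = 1
    anchors: tuple[int, ...] = DEFAULT_HUE_ANCHORS
    control_anchors: tuple[int, ...] = CONTROL_HUE_ANCHORS
    tau: float = 0.3
    rho: float = 3.0
    anchor_strength: float = 3.0
    generations: int = 13
    design: str = "paper"
    max_rotation: int = 20
    landmark_offsets: tuple[int, ...] = (5, 15, 20)
    iteration_window: tuple[int, int] = (4, 13)
    welch: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "anchors", "control_anchors", "landmark_offsets",
                    "iteration_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def learner(self) -> ExemplarLearner:
        return ExemplarLearner(tau=self.tau, rho=self.rho,
                               anchor_strength=self.anchor_strength,
                               anchors=self.anchors)


@dataclass
class StudyReport:
    config: StudyConfig
    seed: int
    chains: list[ChainRecord]
    convergence: ConvergenceCurve
    rotation: RotationProfile
    reference_comparison: CorpusComparison
    control_comparison: CorpusComparison
    closest_languages: dict[str, str]

    def summary(self) -> dict:
        conv = self.convergence
        return {
            "seed": self.seed,
            "n_chains": len(self.chains),
            "n_random_chains": sum(1 for c in self.chains
                                   if c.initial_kind == "random"),
            "generations": self.chains[0].n_generations,
            "first_iteration_mean_vi": float(conv.mean_vi[0]),
            "final_iteration_mean_vi": float(conv.mean_vi[-1]),
            "reference_pairwise_vi": conv.baseline,
            "convergence_paired_t": conv.first_vs_last.as_dict(),
            "convergence_spearman": {"rho": conv.spearman_rho,
                                     "p": conv.spearman_p},
            "rotation_offset0_vi": float(self.rotation.mean_vi[0]),
            "rotation_max_offset_vi": float(self.rotation.mean_vi[-1]),
            "rotation_tests": {str(k): v.as_dict()
                               for k, v in self.rotation.landmark_tests.items()},
            "reference_comparison": self.reference_comparison.as_dict(),
            "control_comparison": self.control_comparison.as_dict(),
            "closest_languages": self.closest_languages,
        }


def run_full_study(config: Optional[StudyConfig] = None, seed: int = 0,
                   out_dir: Optional[str] = None) -> StudyReport:
    """Generate corpora, run the 30-chain design, and perform all three
    analyses; fully reproducible from (config, seed)."""
    config = config or StudyConfig()
    grid = build_wcs_array()
    log.info("generating reference corpus (%d languages)", config.n_languages)
    reference = generate_synthetic_corpus(
        n_languages=config.n_languages, k_range=config.k_range,
        speakers_per_language=config.speakers_per_language,
        noise_eps=config.noise_eps, seed=int(chains_mod.rng_for(seed, "reference").integers(2 ** 31)),
        grid=grid, anchors=config.anchors,
        boundary_jitter=config.boundary_jitter,
        lightness_split_prob=config.lightness_split_prob)
    log.info("generating control corpus")
    control = generate_synthetic_corpus(
        n_languages=config.n_languages, k_range=config.k_range,
        speakers_per_language=config.speakers_per_language,
        noise_eps=config.noise_eps, seed=int(chains_mod.rng_for(seed, "control").integers(2 ** 31)),
        grid=grid, anchors=config.control_anchors,
        boundary_jitter=config.boundary_jitter,
        lightness_split_prob=config.lightness_split_prob)
    if config.design != "paper":
        raise ValueError(f"unknown design {config.design!r}")
    design = build_experiment_design(int(chains_mod.rng_for(seed, "design").integers(2 ** 31)),
                                     k_range=config.k_range)
    learner = config.learner()
    log.info("running %d chains x %d generations", len(design), config.generations)
    records = run_design(design, grid, learner, config.generations)
    random_records = [r for r in records if r.initial_kind == "random"]
    log.info("convergence analysis")
    convergence = convergence_analysis(random_records, reference)
    log.info("rotation analysis")
    rotation = rotation_analysis([r.final for r in random_records], reference,
                                 config.max_rotation, config.landmark_offsets)
    reference_cmp = second_corpus_comparison(random_records, reference)
    control_cmp = second_corpus_comparison(random_records, control)
    window = (min(config.iteration_window[0], config.generations),
              min(config.iteration_window[1], config.generations))
    closest = {r.chain_id: closest_language(r, reference, window)
               for r in random_records}
    report = StudyReport(config, seed, records, convergence, rotation,
                         reference_cmp, control_cmp, closest)
    if out_dir is not None:
        _write_report(report, reference, out_dir, learner)
    return report


def _write_report(report: StudyReport, reference: SpeakerCorpus, out_dir: str,
                  learner: ExemplarLearner) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.convergence.to_frame().to_csv(
        os.path.join(out_dir, "convergence.tsv"), sep="\t", index=False,
        lineterminator="\n")
    report.rotation.to_frame().to_csv(
        os.path.join(out_dir, "rotation.tsv"), sep="\t", index=False,
        lineterminator="\n")
    chain_vi_table(report.chains, reference).to_csv(
        os.path.join(out_dir, "chain_vi.tsv"), sep="\t", index=False,
        lineterminator="\n")
    write_chains(report.chains, os.path.join(out_dir, "chains"),
                 learner.params())
    reference.to_tsv(os.path.join(out_dir, "reference_corpus.tsv"))
    summary = {"config": report.config.as_dict(), **report.summary()}
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    _plots(report, out_dir)


def _plots(report: StudyReport, out_dir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conv = report.convergence
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(conv.iterations, conv.mean_vi, yerr=conv.sd_vi, marker="o",
                capsize=2, label="chains vs reference")
    if conv.baseline is not None:
        ax.axhline(conv.baseline, ls="--", color="grey",
                   label="reference between-language VI")
    ax.set_xlabel("iteration")
    ax.set_ylabel("mean VI (nats)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "convergence.png"), dpi=150)
    plt.close(fig)

    rot = report.rotation
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(rot.offsets, rot.mean_vi, marker="o")
    ax.set_xlabel("rotation (hue columns)")
    ax.set_ylabel("mean VI (nats)")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "rotation.png"), dpi=150)
    plt.close(fig)
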