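# colorchains

Cultural transmission of colour-term systems, simulated and measured.

Languages with few colour words partition colour space in strikingly
similar ways across unrelated societies. One candidate explanation is
that the biases of individual learners — amplified generation after
generation as each person learns the lexicon from the previous one —
are enough to produce these universals, without any selection between
competing languages. `colorchains` packages the computational side of
that argument for researchers in cultural evolution and cognitive
science:

* a model of the standard 330-chip colour stimulus array (40 circular
  hue columns × 8 lightness rows, plus 10 achromatic chips);
* naming systems as partitions of the array, with the hue / lightness /
  random initial-partition generators used to seed transmission chains;
* **variation of information** (VI) as the distance between two naming
  systems `C`, `C'` of the same chips:
  `VI(C, C') = H(C) + H(C') − 2 I(C, C')` (nats), a metric on
  partitions, with the two-stage speaker-then-language averaging used
  to compare a system against a multi-language survey corpus;
* an iterated-learning simulator: 30 chains × 13 generations, each
  learner trained on `6·k` labelled chips from its predecessor
  (`k` = number of terms, 2–6), with a pluggable exemplar learner
  standing in for human participants;
* a synthetic survey-style reference corpus (110 languages × 10
  speakers by default) whose category boundaries share a fixed set of
  canonical hue anchors — the stand-in for cross-language universals;
* the theory underneath: replicator dynamics with mutation
  `dx_i/dt = Σ_j q_ij f_j x_j − φ x_i`, whose neutral case (`f ≡ 1`)
  converges to the leading eigenvector of `Q` — the stationary
  distribution of the iterated-learning Markov chain, which for
  Bayesian posterior-sampling learners equals their prior. The package
  verifies all three identities by exact enumeration on a small ring
  hypothesis space.

## Worked example

```python
import numpy as np
from colorchains import (build_wcs_array, ExemplarLearner,
                         build_experiment_design, run_design,
                         generate_synthetic_corpus)
from colorchains.pipeline import convergence_analysis, rotation_analysis

grid = build_wcs_array()
corpus = generate_synthetic_corpus(n_languages=40, speakers_per_language=5,
                                   seed=11)
design = [c for c in build_experiment_design(7) if c.initial_kind == "random"]
chains = run_design(design, grid, ExemplarLearner(), generations=13)

curve = convergence_analysis(chains, corpus)
print(np.round(curve.mean_vi, 3))
print("baseline", round(curve.baseline, 3),
      "paired t", round(curve.first_vs_last.t, 2),
      "spearman", round(curve.spearman_rho, 3))

profile = rotation_analysis([c.final for c in chains], corpus)
print("rotation argmin", int(np.argmin(profile.mean_vi)),
      "t(0 vs 20)", round(profile.landmark_tests[20].t, 2))
```

prints

```
[2.475 2.167 2.027 1.908 1.828 1.78  1.777 1.684 1.631 1.582 1.567 1.589
 1.572 1.565]
baseline 1.26 paired t 12.4 spearman -0.978
rotation argmin 0 t(0 vs 20) -4.61
```

The first line is the mean VI between the 20 random-initial chains and
the reference corpus at iterations 0–13: chains start far from the
corpus (2.48 nats) and descend toward the corpus's own
between-language VI (1.26 nats); the paired t on initial vs final
per-chain VI and the Spearman trend quantify the decline. The rotation
profile is minimized at offset 0 and significantly worse at a 20-column
hue rotation (negative t: the unrotated fit is better), showing the
convergence reflects *where* category boundaries sit on the hue circle,
not mere regularity.

The same analyses are available from the shell:

```
colorchains full-study --seed 1 --out study/
colorchains dynamics --ring-n 5 --data-size 3 --out dyn/
```

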