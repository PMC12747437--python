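# lear

Localization-error correction for chromatin tracing and other multi-loci
microscopy — **L**oci **E**nabled **A**dvanced **R**esolution.

Chromatin tracing maps the 3D positions of many identifiable genomic loci
across thousands of single cells, but 25–100 nm localization errors blur
exactly the distance range where enhancer–promoter biology happens,
flattening contact-frequency maps and all but erasing multi-way contacts.
`lear` corrects the localizations *after the fact*, using only the data
itself plus an estimate of the localization error.

## The idea

With observed positions `O^α = T^α + ε^α` and independent errors, the
variance of the displacement between two loci decomposes as

    Var(O^α − O^β) = Var(T^α − O^β) + Var(ε^α)

so the error-free *goal variance* `μ_{α,β} = Var(O^α − O^β) − Var(ε^α)` is
computable for every partner β. Adjusted positions `A^α = O^α + C^α` are
found by maximizing

    log l[A^α] = Σ_β log N( Var(A^α − O^β) | μ_{α,β}, σ_{α,β} )

with a seeded stochastic descent, independently per locus and imaging
dimension. The more loci imaged and the tighter their spacing, the more
constraints, and the larger the improvement. The package also ships the
surrounding machinery: error-STD estimation from repeat-imaged loci (or a
worst-case bound without them), off-target and detection-efficiency
filtering, Gaussian-chain simulators for validation, and pairwise /
3-way / 4-way contact-frequency analysis with an independence baseline
for cooperativity.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from lear import (SimulationSpec, generate_polymer_traces, add_localization_error,
                  ErrorModel, OptimizerConfig, run_lear, relative_error_per_locus,
                  contact_frequency)
from lear.benchmark import frobenius_map_distance

# a 100-locus chain at 1 kb-like compaction, 500 traces, 50 nm noise
gt = generate_polymer_traces(SimulationSpec(n_loci=100, n_traces=500, seed=1))
noisy = add_localization_error(gt, 50.0, seed=2)

em = ErrorModel.uniform(100, [50.0, 50.0, 50.0])     # known injected sigma
adjusted, diag = run_lear(noisy.observed, em, OptimizerConfig(seed=3))

rel = relative_error_per_locus(adjusted, noisy.observed, noisy.truth)
print(f"relative error: {np.nanmean(rel):.3f}")

truth_map = contact_frequency(gt.truth, 150.0)
pre  = frobenius_map_distance(contact_frequency(noisy.observed, 150.0).freq, truth_map.freq)
post = frobenius_map_distance(contact_frequency(adjusted, 150.0).freq, truth_map.freq)
print(f"contact-map error: {pre:.2f} -> {post:.2f}")
```

prints

```
relative error: 0.712
contact-map error: 13.77 -> 1.67
```

i.e. the corrected localizations carry ~29% less error than the raw ones,
and the 150 nm contact map moves from badly flattened to nearly on top of
the ground-truth map. Larger errors on the same data are corrected
relatively *more* (the constraint gets stronger as the error grows
relative to inter-locus distances); coarser-resolution data sees smaller
gains.

A command-line interface mirrors the pipeline
(`lear simulate | filter | estimate-error | correct | contacts |
benchmark`); see `lear --help`.

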