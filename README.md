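# intmm — enzyme kinetics from single-time-point measurements

`intmm` is a simulation and estimation toolkit for the question every
discontinuous enzyme assay runs into: what happens to the Michaelis–Menten
parameters if you measure the product at **one** time point per substrate
concentration, after a **large** fraction of the substrate has been
converted, instead of measuring true initial rates?

It is aimed at enzymologists whose assays are slow or expensive per point
(HPLC, electrophoresis, radiometric readouts) or who must work near the
detection limit, where the textbook "use only the first 10% of the reaction"
rule is impractical.

## The model

For an irreversible single-substrate reaction with no product or excess-
substrate inhibition and [E]₀ ≪ [S]₀, the initial rate follows the
Henri–Michaelis–Menten (HMM) hyperbola

    v = V·[S]₀ / (Km + [S]₀),        V = kcat·[E]₀,

and the whole progress curve follows its integrated form

    t = [P]/V + (Km/V)·ln([S]₀ / ([S]₀ − [P])).

The package provides:

* **Exact simulation** of progress: the forward time solver above, and its
  closed-form inversion via the Lambert W function,
  [S](t) = Km·W((S₀/Km)·e^{(S₀−Vt)/Km}) (a bracketing bisection solver is
  kept alongside as an independent cross-check).
* **Sampling plans**: the *constant-conversion* plan (every [S]₀ read at the
  same fractional conversion) and the *constant-time* plan (every [S]₀ read
  at one shared clock time — the practical one).
* **The bias of the naive analysis**: treating the chord [P]/t as if it were
  v and fitting the hyperbola (directly, or through the Hanes–Woolf
  linearisation [S]₀/v = (Km+[S]₀)/V) gives *apparent* parameters V_app and
  (Km)_app that are systematically inflated — mildly for V, strongly for Km
  — in a way that depends only on the design. `bias_table` tabulates this,
  and `correct_apparent` inverts it numerically.
* **The unbiased analysis of the same data**: the integrated equation
  rearranged to [P]/t = V − (Km/t)·ln([S]₀/([S]₀−[P])) is a straight line in
  observable quantities; ordinary least squares on it returns the true V
  (intercept) and Km (−slope) at any conversion.
* **Error propagation**: bounded uniform error models (relative, or absolute
  scaled to the lowest-[S]₀ reading) and replicate studies summarising
  ranges, largest standard errors and replicate means per condition.
* **An end-to-end experimental pipeline**: a synthetic generator of
  nitrocefin-like photometric time courses (β-lactamase hydrolysis,
  V = 33 µM/min, Km = 29 µM, mixing dead time of several seconds), dead-time
  preprocessing that recovers the effective [S]₀ as (final − first reading),
  and consistency diagnostics comparing apparent and integrated estimates.

## Worked example

Simulate a constant-time plate on the reference grid ([S]₀ = 0.35…2.45 in Km
units, V = Km = 1) read at the time where the lowest [S]₀ reaches 50%
conversion, then fit it three ways:

```sh
$ intmm simulate -f 0.5 --out sim.csv
$ intmm fit sim.csv
     method     V      se_V    Km     se_Km  ratio  n
 hyperbolic 1.114   0.01488 1.532   0.04168  0.727  7
hanes_woolf 1.125   0.01607 1.566   0.04355 0.7182  7
 integrated     1 2.863e-16     1 5.402e-16      1  7
consistency: V_app/V = 1.125 (expected 1.125), Km_app/Km = 1.566 (expected 1.566)
```

Reading this: mistaking [P]/t for an initial rate overestimates V by ~12%
and Km by ~57% at this conversion, while the integrated-equation fit of the
*same seven numbers* returns the true parameters exactly. The consistency
line compares the apparent/integrated ratios with the values predicted by
re-simulating the matched design — agreement means the data are consistent
with irreversible, uninhibited HMM kinetics; ratios below 1 or far from the
prediction would flag inhibition or enzyme inactivation.

The full bias table (`intmm biastable`), Monte Carlo studies
(`intmm montecarlo --seed 1 --out study.tsv`), bias-map inversion
(`intmm correct --v-app 1.268 --km-app 2.210 --fraction 0.7`) and the
synthetic experimental pipeline (`intmm fixture` → `intmm preprocess` →
`intmm fit`) are available as library functions and CLI commands alike.

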