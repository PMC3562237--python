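# grm — generalized recruitment model of promoter complex assembly

Gene transcription starts with protein complexes assembling and disassembling
at promoter sites. Two classes of experiments paint conflicting pictures of
that process: ChIP time courses suggest a strictly ordered, *sequential
recruitment* (SR) of factors, while GFP/FRAP imaging suggests highly
stochastic, *probabilistic recruitment* (PR). `grm` implements a generalized
recruitment model that spans the whole range between the two, predicts what a
ChIP experiment would measure for each scenario, and implements the
de-synchronization experiment that can discriminate them.

## The model

The recruitment process is a continuous-time Markov chain on N "landmark"
states S₀ … S₍N₋₁₎ arranged on a circle (state N−1 wraps to 0, the cleared
promoter). Transitions i→j carry rates λᵢⱼ; waiting times are exponential.
The population state distribution pᵢ(t) obeys the master equation

    dpᵢ/dt = Σⱼ λⱼᵢ pⱼ − pᵢ Σⱼ λᵢⱼ .

A constant binary binding matrix P (protein × state) says which proteins are
promoter-bound in which state; the predicted ChIP concentration (fraction of
input) of protein p is the contraction

    c_p(t) = Σᵢ P_pi pᵢ(t).

Each landmark transition is interpolated by m ChIP-invisible substeps, making
the landmark waiting time Erlang(m, mλ) — mean 1/λ, variance 1/(mλ²). For
large m the cycle runs like a clockwork: an initial distribution advects
around the circle with frequency ω = 2πλ/N without changing shape. Reversible
steps (forward λ₊, backward λ₋ < λ₊) reduce, for large N, to a Fokker–Planck
equation with drift v = λ₊ − λ₋ and diffusion D = (λ₊ + λ₋)/2; short-range
extra transitions merely rescale the effective frequency, while *long-range*
shortcuts (span s, rate λ_s, diffusion contribution s²λ_s/2) visibly broaden
the population and change the dynamics qualitatively.

The discriminating observation: a de-synchronized cell population (uniform
phase distribution) is stationary for SR — its ChIP signal is flat — but not
for PR with shortcuts, where it shows transient oscillations. With very many
shortcuts every initial condition relaxes almost immediately.

## Worked example

Run the bundled one-shortcut scenario (N = 200 cycle at unit rate, one
long-range backward shortcut with embedded jump probability 0.3, three
proteins bound in windows of 40 states, three initial conditions):

```bash
grm scenario fig5_one_shortcut --out out/fig5
```

prints

```
verdict: PR_shortcuts (nominal period 100.168)
          random         P1: period=     199 amp=0.0336 decay=0.00292 varfrac=0.56 p=0.005
          random         P2: period=     205 amp=0.0387 decay=0.00423 varfrac=0.42 p=0.010
          random         P3: period=     196 amp=0.0427 decay=0.00487 varfrac=0.49 p=0.010
        gaussian         P1: period=     100 amp=0.2955 decay=0.000228 varfrac=0.64 p=0.005
        gaussian         P2: period=     100 amp=0.3647 decay=6.84e-05 varfrac=0.81 p=0.005
        gaussian         P3: period=     100 amp=0.2426 decay=3.65e-21 varfrac=0.72 p=0.005
         uniform         P1: period=     200 amp=0.0462 decay=0.00349 varfrac=0.97 p=0.005
         uniform         P2: period=     199 amp=0.0419 decay=0.00357 varfrac=0.97 p=0.005
         uniform         P3: period=     200 amp=0.0397 decay=0.00356 varfrac=0.97 p=0.005
```

Reading this: the synchronized (Gaussian) population oscillates strongly
(amplitude ≈ 0.3 of input, negligible decay) — exactly what a pure
sequential cycle would also show, so it proves nothing. The de-synchronized
conditions (uniform, random) are *not* flat: they oscillate with small but
significant amplitude (≈ 0.04, permutation p ≈ 0.005) that decays towards the
steady state — the fingerprint of a long-range shortcut, hence the verdict
`PR_shortcuts`. For a pure cycle (`grm scenario fig3_sr …`) the uniform
condition is constant to machine precision and the verdict is `SR`.

The output directory contains `network.tsv`, `binding.csv`, one
`chip_<condition>.csv` per initial condition, `report.json` and a
`provenance.json` sidecar. The same analysis runs on your own measured ChIP
tables:

```bash
grm classify gaussian=sync.csv uniform=desync.csv --out verdict.json
```

From Python, the six bundled scenarios and all primitives are importable:

```python
from grm import build_ps2_scenario, make_initial_condition, \
    clockwork_propagate, chip_signal, detect_oscillations

net, binding = build_ps2_scenario(100, clearance_probability=0.5)
ic = make_initial_condition("gaussian", net)
_, dists = clockwork_propagate(net, ic.distribution(), 1600)
reports = detect_oscillations(chip_signal(binding, dists), seed=0)
print(reports["A"].period / reports["B"].period)   # 2.0016
```

This is the double-transcription-cycle promoter with probabilistic clearance:
the persistent (TBP-like) factor's dominant ChIP period is twice the cycling
factor's even though promoter clearance is a coin flip, showing that the
experimentally observed even/odd cycle alternation does not have to be
deterministic.

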