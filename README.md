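# forkdyn

Live-cell quantification of replication-fork stalling and restart from
PCNA/RPA1 time-lapse imaging.

When replication forks stall under nucleotide depletion (hydroxyurea, HU),
two things happen on very different clocks: PCNA — the sliding clamp whose
focal signal reports ongoing DNA synthesis — leaves replication foci
within minutes, while RPA — the ssDNA-binding complex — accumulates in the
same foci for tens of minutes as unwinding outruns synthesis. `forkdyn`
turns multi-channel time-lapse movies of nuclei into quantitative fork
biology:

* **bound fractions** from diffuse-pool photometry: with D_t the
  background-corrected intensity of a foci-free nuclear region and T_ref
  its level when the whole pool is diffuse, the bound intensity is
  E_t = T_ref − D_t and the bound fraction F_t = E_t / T_ref;
* **absolute stoichiometry**: G_t = F_t · N / N_forks complexes per fork
  (N = 865,300 PCNA homotrimers or 926,424 RPA heterotrimers per nucleus,
  ~4000 active forks) and H_t = 30 nt · G_t of RPA-covered ssDNA per fork;
* **kinetics**: single-exponential half-time fits
  (y = r + (a−r)e^(−kt), t½ = ln2/k) for dissolution/accumulation, rate
  and plateau estimation;
* **FRAP**: the four-step normalization (background subtraction,
  pre-bleach scaling, reference-focus ratio, affine pinning to 0/1), a
  two-component decomposition A_f(1−e^(−k_f t)) + A_s(1−e^(−k_s t)) into
  freely diffusing, bound-exchanging and immobile fractions, and exchange
  rates in complexes per minute;
* **single-focus validation**: tracked foci, 7×7 kymogram strips, and the
  radius-3.5 px circle trace Q_t/nM_t that cross-checks the diffuse-pool
  measurement;
* a **synthetic-movie generator** with exact ground truth (piecewise
  exponential schedules, conservation of total fluorescence, Poisson +
  Gaussian camera noise, FRAP bleach events), so the whole chain is
  testable without microscopy data.

It is written for people quantifying replication-stress imaging — or
benchmarking such pipelines — who want every step, from pixels to
"complexes per fork", inspectable and tested.

## Worked example

Simulate ten noisy two-channel cells at the standard schedule (15 min
baseline, 60 min HU at 30 s frames, focus SNR ≈ 10), quantify and fit:

```python
from forkdyn.pipeline import simulate_stalling_batch, summarize_batch

batch = simulate_stalling_batch(10, seed=20, washout_min=0.0)
df = summarize_batch(batch, {"pcna": "decay", "rpa1": "accumulation"})
print(df.groupby("channel")[["t_half_min", "baseline_fraction", "end_hu_fraction"]].mean())
```

```
         t_half_min  baseline_fraction  end_hu_fraction
channel
pcna       2.037424           0.269792        -0.003162
rpa1      24.910971          -0.000020         0.342881
```

Ground truth was t½ = 2.1 min dissolution with 27% of PCNA bound at
baseline, and t½ = 23.9 min accumulation reaching ~34% of RPA bound at the
end of treatment: the pipeline recovers all four within a few percent.
Convert the RPA plateau into physical units:

```python
from forkdyn.stoichiometry import complexes_per_fork, ssdna_per_fork

g = complexes_per_fork(0.35, species="rpa")   # 81.06 complexes per fork
print(g, ssdna_per_fork(g))                   # 81.0621  2431.863 nt ssDNA per fork
```

## The analysis scripts

`analysis/01…06` run the packaged study end to end: simulate HU and
HU+ATR-inhibited batches, measure bound fractions, fit half-times and
rates, convert to complexes/ssDNA per fork, run the FRAP study, and
validate the single-focus route against the diffuse-pool route. Tables
land in `results/`, movies in `scratch/`. A `forkdyn` CLI wraps the same
steps for file-based use (`forkdyn simulate`, `quantify`, `frap`, `track`,
`report`).

## Layout

```
src/forkdyn/      library: schedule, simulate, movie, roi, stoichiometry,
                  kinetics, frap, tracking, pipeline, cli
analysis/         numbered study scripts (simulate → quantify → fit → convert
                  → FRAP → single-focus validation)
scripts/          acceptance.py (see above)
tests/            pytest suite, including end-to-end recovery tests
docs/methods.md   model, assumptions, parameter choices, limitations
```
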