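# benthotrack

Habitat- and movement-selection analysis for benthic animals tracked by
fine-scale acoustic positioning over a classified seabed substrate map
(a *benthoscape*). Built for movement ecologists working with
positioning-array telemetry (e.g. lobster tracked on a receiver grid)
who want the full chain — positioning quality control, track
regularization, resource selection functions, integrated step-selection
functions, and substrate-map accuracy assessment — as tested,
reproducible Python, with a synthetic-data generator that makes every
stage verifiable by parameter recovery.

## The statistics at the core

**Resource selection (RSF).** Presences vs pseudo-absences (10 per
presence, drawn from each individual's minimum convex polygon) in a
logistic regression `presence ~ substrate + (1 | individual)`, refit 100
times on 100-point-per-individual subsets to blunt spatial
autocorrelation. Exponentiated class coefficients give relative
selection strength (RSS) against the reference substrate; median and IQR
over reruns summarize each class.

**Integrated step selection (iSSF).** Per individual, a tentative
movement kernel — gamma(k, θ) step lengths, von Mises(0, κ) turning
angles — is fitted to observed steps; each observed step is matched with
100 random alternatives from that kernel, and a conditional logistic
regression is fitted:

    case ~ end substrate + log(sl) + cos(ta)
           + start substrate:log(sl) + start substrate:cos(ta) + strata

with a 1000-replicate stratum bootstrap for uncertainty. The movement
coefficients update the kernel per start substrate
(shape\* = k + β_log sl + interaction; κ\* likewise with cos ta), and
signs read as behaviour: shorter steps = more resident, lower
directionality = more turning.

The estimating engines (gamma and von Mises MLEs, Newton conditional
logistic regression with a separation guard, Laplace random-intercept
logistic regression, stratum bootstrap) are implemented in
`benthotrack.stats` directly on their estimating equations; see
`docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run one synthetic study end to
end; each prints what it found and writes its tables under
`results/pipeline/`:

```bash
python analysis/01_simulate.py   # benthoscape + tracks with known selection
python analysis/02_qc.py         # HPE cut-off candidates, HPEm report, filtering
python analysis/03_prep.py       # 10-min bursts, steps, substrate covariates
python analysis/04_rsf.py        # pseudo-absences, 100x subsample-refit, RSS
python analysis/05_issf.py       # per-individual iSSF + bootstrap + kernels
python analysis/06_classify.py   # PCA + clustering + accuracy assessment
python analysis/07_report.py     # verdict against the generating truth
```

With the bundled configuration (5 individuals, 1500 steps each,
generating selection β = +0.8 for mixed sediments and −0.4 for coarse
sediments against the silt/mud-with-gravel reference), the drivers
print, among other things:

```
per-deployment 95%-retention cut-off candidates: {'D1': 24.58}
  D1: HPEm median 2.28 m, p90 6.37 m, p95 8.39 m (retention 0.950 ...)
final cut-off HPE < 25.0: 22486 animal positions -> 17260 retained
...
median RSS per substrate (reference = 'Silt/mud with <= 50% gravel'):
  Coarse sediments                      median 0.59 (IQR 0.51-0.69); generating RSS 0.67
  Mixed sediments with a veneer of mud  median 1.57 (IQR 1.37-1.92); generating RSS 2.23
...
  BL 027 (991 strata): end_0=-0.48 (SD 0.22), end_2=0.52 (SD 0.13), ...
```

Reading this: the QC stage reproduces the designed ~2.4 m-median error
and its 95%-retention cut-off lands at ≈ 25; the RSF and iSSF both
recover the *direction* of the generating selection (avoidance of
coarse sediments, preference for mixed sediments), with magnitudes
attenuated toward zero because observed positions carry positioning
error comparable to the raster cell size — the recovery experiments on
true tracks (below) show the estimators themselves are unbiased.

## Layout

    src/benthotrack/      raster, simulate, qc, trackprep, stats/, rsf,
                          issf, classify, experiments, pipeline, cli
    analysis/             numbered drivers for the worked study
    tests/                pytest suite (unit + property + acceptance)
    scripts/acceptance.py verification quantities as JSON
    docs/methods.md       models, assumptions, numerical choices, limits

A `benthotrack` CLI (`benthotrack run-all --demo`, plus per-stage
subcommands) wraps the same pipeline stages.
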