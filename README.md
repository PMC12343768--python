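# idrcond

Analysis pipeline for studying how the charge patterning of
intrinsically disordered regions (IDRs) shapes transcription-factor
condensate behavior: sequence-grammar z-scores and charge profiles,
well-mixed-charge sequence design, mean-field IDR–IDR interaction maps,
single-molecule residence-time survival analysis, nuclear cluster
quantification, and condensate recruitment kinetics with photobleach
correction. Synthetic-data generators with known ground truth stand in
for raw microscopy, so every stage of the pipeline is testable
end-to-end.

Intended users: quantitative cell biologists and biophysicists working
on transcriptional condensates (YAP/Mediator/Pol II-type systems) who
need a reproducible desk-scale implementation of these analyses.

## The quantities at the core

**Charge patterning (kappa-style) statistic.** For disjoint residue
groups X, Y (e.g. negative {D, E} vs positive {K, R}) and window size
g, each full window i gets

σᵢ = (f_{X,i} − f_{Y,i})² / (f_{X,i} + f_{Y,i})   (σᵢ = 0 if the window has no X∪Y),

σ̄ is the same quantity from whole-sequence fractions, and

δ_g = ⟨(σᵢ − σ̄)²⟩ᵢ,  δ = mean over g ∈ {5, 6}.

Blocky (segregated) arrangements give large δ, well-mixed ones small δ.
Significance is the z of δ against uniform shuffles of the sequence
(composition-preserving null); composition features (amino-acid and
group fractions, FCR, NCPR) are scored against an IDRome background.

**Well-mixed-charge design.** Within each IDR, charged residues
(D/E negative; K/R/H positive for extraction, H scored 0 for the net
charge) are redistributed over the existing charged positions by
alternating draws from the negative and positive pools in N→C order,
with selected native negatives anchored — conserving composition and
per-IDR net charge exactly while dispersing the charge blocks.

**Mean-field interaction maps.** For windows A, B (length 31) of two
sequences, ε(A, B) = ⟨w(a, b)⟩ over all residue pairs, with a pluggable
symmetric 20×20 pair-weight matrix (negative = attractive); per-residue
attractive vectors average min(ε, 0) over all cells containing the
residue.

**Dwell-time survival.** Track dwell times (gap-inclusive, 150 ms
frames) pool into the empirical survival function S(t) = P(dwell > t),
fit by S(t) = A·e^(−t/τ_ns) + (1−A)·e^(−t/τ_s) with τ_ns < τ_s — a
short-lived non-specific and long-lived specific chromatin-binding
population.

**Clusters and recruitment.** Nuclear clusters are fit by 2D Gaussians
with offset; the 2σ-ellipse integral over unitary (single-molecule)
intensity counts molecules, and nuclei decompose into dense (clusters
with ≥10 molecules) and dilute phases. Condensate recruitment time
courses are filtered (start at t=0, ≥10 frames, area 0.45–1.55 a.u.,
nuclear), corrected by a mono-exponential fit to fluorophore-only
control tracks (non-specific recruitment + photobleaching), gated on
the YAP response at 16 min, and pooled into mean ± SEM curves.

## Worked example

The numbered drivers under `analysis/` run each stage on synthetic data
and write tables under `results/`. For instance:

```bash
$ python analysis/04_dwell_times.py
9148 dwells -> A=0.67, tau_ns=1.27 s, tau_s=7.06 s (truth 0.70 / 1.2 s / 7 s)
bin fractions: {'<1.2s': 0.397, '>=1.2s': 0.603, '>=7s': 0.126, '>=10s': 0.08}
fold changes (perturbed / control):
  <1.2s: 1.17 (p=6.32e-06)
  >=1.2s: 0.87 (p=6.32e-06)
  >=7s: 0.49 (p=1.66e-06)
  >=10s: 0.47 (p=2.96e-06)
```

10⁴ dwell times are drawn from the two-exponential mixture, rendered as
a tracker-style table (plus 200 single-frame noise detections, which
the extraction filters out), and re-fit: the recovered time constants
(1.27 s / 7.06 s) match the generating values within a few percent, and
halving the slow population in a perturbation arm halves the ≥7 s and
≥10 s bin fractions (fold ≈ 0.5) while barely touching sub-second
events — the signature of a condensate-dependent specific-binding
population.

```bash
$ python analysis/06_recruitment.py
med1: kept 80/80 tracks, 40 gated; control residual +0.00 a.u.; final/max = 0.90
pol2: kept 80/80 tracks, 40 gated; control residual +0.00 a.u.; final/max = 0.42
pol2_drb: kept 80/80 tracks, 40 gated; control residual +0.00 a.u.; final/max = 0.94
DRB difference: |mean| 2.0 a.u. before 12 min, +60.9 a.u. after 40 min (elongation block keeps Pol2 high)
```

The Mediator-like partner sustains (final/max = 0.90) while the
Pol2-like partner adapts (0.42) under transcriptional negative
feedback; blocking elongation at 12 min removes the feedback, and the
treated-minus-vehicle difference curve is flat before and positive
after the cut.

A thin CLI (`idrcond simulate|grammar|design|intermap|dwell|clusters|recruit`)
exposes the same stages on files, stamping every output with a JSON
manifest (parameters, seeds, input hashes).

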