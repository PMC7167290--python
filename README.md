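# ublsig

Discovery and scoring of **ubiquitin / SUMO-1 conjugation signatures of
AML chemoresistance** from two-channel protein-array experiments, with a
multiplexed bead-assay quantification stage and a synthetic-data module
that makes the whole pipeline testable end to end.

## The problem

Acute myeloid leukemia (AML) patients receive induction chemotherapy
(an anthracycline plus cytarabine) with no fast test to predict who will
respond. One proposed class of biomarkers is *enzymatic*: incubate a
patient's cell extract with arrays of recombinant proteins under
UbL-conjugation-permissive conditions and measure, per protein, how much
ubiquitin or SUMO-1 its extract conjugates onto it. Chemoresistant cells
carry dysregulated E1/E2/E3 cascades, so the conjugation pattern itself
is the readout.

This package implements that analysis workflow for anyone working with
such data:

1. **Array I/O** (`ublsig.gpr`, `ublsig.matrix`) — parse GenePix-style
   GPR scan files into a proteins x arrays intensity matrix with array
   metadata (cell line, condition, experiment batch, NEM-control flag).
2. **Preprocessing** (`ublsig.preprocess`) — background correction
   (`max(F - B, floor)`), duplicate-spot averaging, within-experiment
   quantile normalization, cross-experiment batch adjustment
   (log2 median-centering, or an empirical-Bayes location/scale variant).
3. **Statistics** (`ublsig.stats`) — self-contained Welch / one-sample /
   paired t tests, Wilcoxon–Mann–Whitney and Wilcoxon signed-rank tests
   with exact small-sample null distributions.
4. **Signature calling** (`ublsig.signature`) — stage 1: a protein is
   *modified* when both Welch and Mann–Whitney reject (p < 0.05) against
   NEM-treated control arrays and its mean intensity clears 800 a.u.;
   stage 2: *differentially modified* when the signed-rank and one-sample
   t tests reject on log2 resistant/parental ratios and the geometric-mean
   ratio is outside [0.8, 1.25] (pooled analysis) or [0.66, 1.5] (per cell
   line x drug). The union of both analyses is the signature.
5. **Scoring** (`ublsig.score`) — a binary-chromosome genetic algorithm
   (40 jittered runs) selects predictive (protein, modifier) variables;
   variables are ranked by selection frequency, cut into nested subsets,
   and evaluated by cross-validated linear discriminant analysis. The
   winning subset's LDA assigns each sample
   `score = α·R1 + β·R2 + … + ω·Rn` and a posterior probability of
   resistance; below 50% ⇒ sensitive, above ⇒ resistant.
6. **Bead assay** (`ublsig.beads`) — gate flow-cytometry events to
   color-coded bead regions, compute median reporter fluorescence (MFI)
   per biomarker, subtract NEM backgrounds, form resistant/parental
   ratios, compare responder vs refractory cohorts (Welch), and flag
   patients with high modification (reference mean + 2 SD on ≥ 1
   biomarker).
7. **Simulation** (`ublsig.simulate`) — generates the full study design
   (3 experiments x [2 cell lines x 3 conditions + 2 NEM controls] = 24
   arrays) as GPR files with planted modified/differential proteins and a
   ground-truth table, plus bead-assay event tables and labeled scoring
   cohorts.

## Worked example

```python
import tempfile
from ublsig.simulate import SimulationConfig, simulate_protoarray_study
from ublsig.gpr import read_gpr
from ublsig.matrix import assemble_matrix
from ublsig.preprocess import preprocess_chain
from ublsig.signature import (call_modified, compute_ratios,
                              call_differential_global,
                              call_differential_separated, merge_signature)

cfg = SimulationConfig(n_proteins=400, rng_seed=7)
with tempfile.TemporaryDirectory() as tmp:
    paths, meta, truth = simulate_protoarray_study(cfg, tmp)
    spots = {p.stem: read_gpr(p) for p in paths}
    matrix = assemble_matrix(spots, meta, cfg.channels)

matrix, report = preprocess_chain(matrix)
calls = call_modified(matrix)
ratios = compute_ratios(matrix, calls)
signature = merge_signature(call_differential_global(ratios),
                            call_differential_separated(ratios))
```

Output of `python examples/01_discovery.py` (this exact computation):

```
arrays: 24, proteins: 400
planted modified (protein, UbL) pairs: 60
called modified: 55 (55 true, 0 false)
differential called: global 5, separated 20
signature: {'SUMO1': 2, 'ubiquitin': 3} -> 5 distinct proteins (planted differential: 6)
```

55 of 60 planted modified proteins are recovered with zero false calls
(the misses sit below the 800 a.u. intensity floor), and 5 of the 6
planted differential proteins make it into the merged signature. The
other `examples/` scripts demonstrate the statistical tests, the GA+LDA
score and the bead assay the same way.

A thin CLI mirrors the pipeline stages:

```bash
ublsig simulate --seed 1 --outdir out/sim
ublsig discover --seed 1 --outdir out/disc
```

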