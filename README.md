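# dmnclass

Task-induced deactivation, pseudo-resting-state functional connectivity and
group classification for blocked-design fMRI — with a fully synthetic
two-group cohort generator so the whole pipeline is testable end-to-end
without any external data.

## What it does

1. **study_design** — data model and I/O (TSV/JSON + sidecar) for blocked
   experimental designs; three built-in canonical designs (sentence, word,
   theory-of-mind) containing 17 rest blocks in total.
2. **synthetic_cohort** — generates a 13 + 14 subject cohort with planted
   effects: group-differential DMN node correlation structure (reduced MPFC
   coupling in one group), group-differential task deactivation amplitudes,
   plus drift, motion-coupled, global and white-noise components. ROI mode
   (2D `(roi, t)` runs, 116 labels) or voxel mode (NIfTI on an MNI-like
   labelled grid).
3. **rest_extraction** — excises rest blocks (first 6 s dropped; for
   short-rest designs the first 6 s of the following task block is
   appended) and collates runs into one 285-volume series per subject with
   full segment provenance.
4. **signal_cleaning** — nuisance regression (6 motion params + mean
   motion, GM/WM/CSF/whole-brain means, per-session trend and intercept)
   and Gaussian smoothing.
5. **deactivation_glm** — HRF-convolved boxcar GLM, contrast t-maps,
   random-effects group t-tests, Benjamini–Hochberg FDR, Monte-Carlo
   cluster-extent thresholds, cluster extraction.
6. **connectivity** — seed-based voxelwise maps for the three deactivation
   seeds (MPFC −1 47 −4; PCC/PrC −5 −49 40; AG −45 −67 36), Fisher r-to-z,
   averaged 3-seed DMN maps, and 102×102 ROI connectivity matrices
   (116-label atlas minus 14 exclusions → 5151 upper-triangle features).
7. **classification** — leave-one-out logistic regression (L2, fold-wise
   standardization), sensitivity/specificity, exact binomial significance,
   top-0.5% informative connections, Bonferroni-corrected per-feature
   group tests.
8. **cli_reporting** — config, orchestration, and the `dmnclass` CLI.

## CLI

```bash
dmnclass demo --seed 7 --effect-size 0.3 --out runs/demo   # end-to-end
dmnclass synthesize --out runs/cohort --seed 7             # write cohort
dmnclass extract-rest --cohort runs/cohort --out runs/rest
dmnclass clean --cohort runs/cohort --out runs/clean
dmnclass deactivation --cohort runs/cohort --out runs/deact
dmnclass connectivity --cohort runs/cohort --out runs/conn
dmnclass classify --cohort runs/cohort --out runs/clf --l2 1.0
```

`demo` is deterministic: the same seed produces byte-identical reports
(`report.json` + `summary.txt`), and the report records every active
design decision (lag, thresholds, HRF, regularization, seeds).

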