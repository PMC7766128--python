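# exobci

A motor-imagery hybrid BCI controller pipeline for a lower-limb exoskeleton,
implemented as a tested Python library + CLI that runs end-to-end on
synthetic EEG — no amplifier or robot required.

The pipeline has three cooperating parts:

1. **EEG decoder** — six-band zero-phase Butterworth filter bank
   (7–9, 10–12, 13–15, 16–20, 21–25, 26–34 Hz), per-band CSP spatial
   filtering with first/last-two component selection (24 log-normalized
   variance features), mutual-information-based best-individual-feature
   (MIBIF) selection (k = 4–10), and a linear SVM. Two binary classifiers
   are trained: Gait-vs-Nothing (`gvn`) and Gait-vs-Sit (`gvs`). Online,
   a 2 s window is re-classified every 0.5 s from 31-channel × 10-sample
   packets at 500 Hz.
2. **Triple-eye-blink (TEB) brain switch** — FP1/FP2 mean, 2–15 Hz IIR
   bandpass, biorthogonal (bior1.5) stationary-wavelet detail enhancement,
   and supra-threshold peak counting in a 1.6 s window sliding by 0.4 s;
   exactly three peaks toggle the decoder.
3. **Buffered finite-state machine** — states SIT → decode(GvN) → STAND →
   decode(GvS) → GAIT with three size-10 command buffers (fill +1 /
   empty −3); a buffer must fill completely before an action
   (stand-up, gait start/stop, sit-down) is issued.

A seeded synthetic EEG module (`exobci.synth`) generates 90-trial cued
training sessions and free-running scenario streams with band-limited
sensorimotor rhythms (attenuated during imagery with class-distinct
spatial/spectral signatures), 1/f background noise, a 60 Hz line component,
and stereotyped single/double/triple eye-blink pulses — so every stage is
testable against known ground truth.

## CLI

```sh
exobci simulate-session --seed 7 --out session.edf           # 90-trial session
exobci train --session session.edf --pair gvn --out gvn.json
exobci train --session session.edf --pair gvs --out gvs.json
exobci evaluate-offline --session session.edf --pair gvn --out gvn_metrics.json
exobci simulate-scenario --seed 21 --out stream.edf          # walk scenario
exobci detect-teb --in stream.edf --calibration baseline.edf --out teb.csv
exobci decode-stream --in stream.edf --model gvn.json --out commands.csv
exobci run-controller --commands commands.csv --teb teb.csv --log trace.csv
exobci run-scenario --in stream.edf --gvn gvn.json --gvs gvs.json \
    --calibration baseline.edf --reference-s 106.5 --out scenario_out/
exobci report --metrics gvn_metrics.json --metrics gvs_metrics.json --out report.json
```

Signals travel as classic EDF (with a `<stem>_events.csv` sibling for
events/trials), models and metrics as JSON, configuration as YAML
(`exobci export-config`).

## Layout

| module | contents |
| --- | --- |
| `exobci.synth` | montage, intent timelines, ERD/blink parameters, generators |
| `exobci.filterbank` | filter bank, CSP, FBCSP features |
| `exobci.mibif` | mutual-information feature ranking/selection |
| `exobci.decoder` | training pipeline, sliding-window stream decoder, model I/O |
| `exobci.teb` | blink-switch preprocessing, calibration, detection |
| `exobci.fsm` | command buffers, controller state machine |
| `exobci.pipeline` | full hybrid chain (decoders + switch + FSM) |
| `exobci.evaluation` | confusion rates, bit rate/ITR, bootstrap accuracy, Fisher maps, ERSP, scenario timing |
| `exobci.edfio`, `exobci.config`, `exobci.cli` | formats, configuration, command line |
| `exobci.wavelets` | undecimated bior1.5 wavelet analysis |
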