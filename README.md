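# knee-adl

Activity-of-daily-living (ADL) recognition from a pair of IMUs embedded in
the femoral and tibial components of a knee prosthesis — plus a synthetic
knee-kinematics simulator that generates the dual-device 50 Hz streams the
pipeline consumes.

The pipeline:

1. **simulate** — generate labeled femoral/tibial 6-channel IMU streams
   (3-axis accelerometer + 3-axis gyroscope at 50 Hz) for eight activities
   (walking, jogging, stair ascent/descent, sitting down, standing up, knee
   bending, standing still), with asynchronous device start-up, sensor
   noise, gyro bias walk, and per-sample dropout.
2. **sync** — bin both asynchronous streams into a shared 100 ms grid
   (keeping the most recent sample per bin), gap-fill short dropouts by
   carry-forward, and cut 30-frame (3 s) 12-channel windows.
3. **filter** — zero-phase Butterworth-magnitude filtering: low-pass on the
   accelerometer channels, high-pass on the gyroscope channels.
4. **features** — per-channel short-time Fourier transform producing a
   log-power 8×8 image per channel (8×8×12 tensor per window).
5. **model** — dual-branch classifier: a two-layer LSTM (384/256 units,
   20%/45% dropout) over the time-domain window, and a CNN (128 3×3
   filters, 2×2 max-pool, 40% dropout, 256-unit position-wise dense) over
   the spectrogram tensor; concatenated, fused through a 256-unit ReLU
   layer and an 8-way softmax. Trained with categorical cross-entropy and
   Adam, early-stopping on validation loss.  The network (including
   backprop) is implemented directly on numpy — no deep-learning framework
   required.
6. **evaluate** — stratified 70/11/19 split (optionally grouped by
   recording to prevent leakage), confusion matrix, per-class
   precision/recall/F1, macro and weighted averages.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which trains the full
benchmark once (a few minutes on one CPU); everything else finishes in
well under a minute.

## CLI

```sh
knee-adl simulate --out data/ --seed 42            # synthetic dataset + manifest
knee-adl prepare  --manifest data/manifest.json --out data/windows.npz
knee-adl train    --windows data/windows.npz --out model/ --seed 42
knee-adl evaluate --model model/ --windows data/windows.npz --out report
knee-adl predict  --model model/ --femoral a.csv --tibial b.csv
knee-adl benchmark --out bench/ --seed 42          # everything end to end
knee-adl validate-config config.yaml
```

All commands accept `--config <yaml>`; see `examples/benchmark.yaml` for
the available sections. A single master `--seed` deterministically derives
all stage seeds — two runs with the same seed produce identical outputs.

## Data formats

Stream CSV: `device_id,t_ms,ax_mps2,ay_mps2,az_mps2,gx_dps,gy_dps,gz_dps`
with strictly increasing integer-millisecond timestamps and fixed 6-decimal
values (byte-stable round-trips).  The dataset manifest is JSON mapping
recording ids to stream pairs and activity labels.  Prepared datasets are
stored as `.npz` (`windows` N×30×12, `spectrograms` N×8×8×12, `labels`,
`groups`) with a JSON parameter sidecar; trained models as a weights `.npz`
plus `model.json` carrying the config, class ordering, and normalization
statistics.
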