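# seqreplay

Decoding-based detection of fast sequential neural reactivation
("replay") in multichannel sensor time series, validated end to end on
synthetic recordings with known ground truth.

The pipeline:

1. **Task structures** (`seqreplay.task`) — state sets for two designs
   whose presentation ("visual") order is a scrambled version of two
   rule-defined 4-state chains, plus position/sequence factor labels.
2. **Synthetic data** (`seqreplay.simulate`) — labeled localizer epochs
   (one evoked spatial pattern per state) and resting recordings with
   injected 4-state replay sequences at a fixed state-to-state lag, a
   10 Hz nuisance oscillation, and white sensor noise.
3. **Preprocessing** (`seqreplay.signal_io`) — band-limited resampling
   (e.g. 600 → 100 Hz) and a first-order IIR high-pass (0.5 Hz), plus
   array I/O (`.npz` + JSON sidecar).
4. **Decoding** (`seqreplay.decoding`) — one L1-regularized binomial
   logistic classifier per state, trained on a single post-onset time
   slice (default 200 ms) with other-state trials and pre-onset null
   segments as negatives; leave-one-trial / leave-one-stimulus
   cross-validation; sensor-subset contribution maps; factor-decoder
   residualization.
5. **Sequenceness** (`seqreplay.sequenceness`) — for each lag Δt, every
   state's reactivation series is regressed on Δt-lagged copies of all
   series (plus nuisance copies at Δt+100 … Δt+600 ms and a constant);
   the coefficient matrix is projected onto a hypothesis transition
   matrix P (Frobenius inner product) to give forward evidence Zf, onto
   Pᵀ for Zb; sequenceness = Zf − Zb.  Significance uses a
   max-over-lags permutation of the state labels.  A length-n variant
   measures extra evidence for 3- and 4-step chains beyond pairwise
   structure.
6. **Replay events** (`seqreplay.events`) — momentary replay strength
   R(t) = Σᵢ (Y·P)(t,i) · Y(t+Δt,i), thresholded at a percentile with a
   100 ms replay-free pre-window; event-locked Morlet time-frequency
   contrasts against a −100…−50 ms baseline; one-sample cluster-based
   sign-flip permutation tests; cross-code lag analyses; onset
   coincidence statistics.
7. **Pipeline** (`seqreplay.pipeline`, `seqreplay.cli`) — a seeded,
   deterministic end-to-end run from a single config.

## CLI

```bash
# full pipeline from a YAML config (all keys optional; see RunConfig)
seqreplay run --config cfg.yaml --seed 1 --out report.json

# or stage by stage
seqreplay simulate --design study1 --seed 1 --lag-ms 50 --out out/sim
seqreplay preprocess out/sim_rest --highpass 0.5 --out out/rest
seqreplay train out/sim_localizer --out out/dec
seqreplay apply out/dec out/rest --out out/Y
seqreplay sequenceness out/Y --matrix rule --spec out/sim_spec.json \
    --perms 100 --out out/seq.csv
seqreplay events out/Y --matrix rule --spec out/sim_spec.json \
    --lag-ms 50 --out out/events.csv
seqreplay tfstats map1.npy map2.npy ... --n-perm 5000
```

`seqreplay run` writes a JSON report with the peak lag, peak
sequenceness, permutation threshold, and event-detection
precision/recall against the injected ground truth; reports are
bit-identical for identical config + seed.

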