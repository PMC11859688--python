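# Methods

## Problem and signal model

An FMCW radar transmits linear chirps of bandwidth `B` over duration `T`
(slope `kappa = B/T`). Mixing the echo of a reflector at range `R` with the
transmit signal produces an intermediate-frequency (IF) beat tone at
`f_b = 2*kappa*R/c`; across successive chirps ("slow time") the phase of
that tone tracks sub-wavelength range changes as

    dphi = 4*pi*dR / lambda,        lambda = c / fc.

At 60.25 GHz (`lambda ≈ 5 mm`) the chest wall's respiratory excursion
(4–12 mm) swings the phase through several multiples of 2*pi, while the
heartbeat (0.2–0.5 mm) contributes a sub-radian ripple. The task is to
recover both rates from the phase of the subject's range bin in the
presence of static clutter, a DC offset, harmonics of both motions, and
additive noise.

## Processing chain

1. **DC / static-clutter removal.** Each fast-time column's mean over slow
   time is subtracted. Per-column (rather than a single global scalar)
   removal zeroes the constant contribution of every static reflector in
   every range bin; the operation is idempotent.
2. **Range FFT and bin selection.** Fast-time DFT per frame (rectangular
   window by default, Hann optional, no zero padding); the target bin is
   the one with maximal mean magnitude over slow time, optionally inside a
   range gate. Ties break to the lowest index.
3. **Phase extraction.** Four-quadrant `atan2(Q, I)` per frame. The plain
   ratio `arctan(Q/I)` loses quadrant information, and unwrapping assumes
   a `(-pi, pi]` input, so the four-quadrant form is used throughout.
4. **Unwrapping.** Cumulative correction: every consecutive step larger
   than `pi` in magnitude shifts all subsequent samples by the appropriate
   multiple of `2*pi`. Single-jump correction would not suffice: the
   respiratory excursion alone wraps the phase many times.
5. **Differencing.** First difference of the unwrapped phase. This
   suppresses residual drift and flattens the otherwise ~30 dB level gap
   between respiration and heartbeat (the difference has gain
   `2*sin(pi*f/fs)`, rising with frequency). No compensating filter is
   applied; the estimator operates on the differenced signal.

## Weighted-PCA separation

The scalar differenced phase `s(t)` is lag-embedded into an `M x L` Hankel
trajectory matrix (`X[i,j] = s[i+j]`, unit hop) — the singular-spectrum-
analysis construction that makes subspace separation of a scalar series
well-posed. After row-mean removal the sample covariance `(1/L) X X^T` is
eigendecomposed (`Q` orthonormal, eigenvalues descending, each vector's
largest-magnitude entry made positive for determinism). Component `i`'s
coefficient series is `y_i(t) = q_i^T (X - mean)`.

Components are assigned to a vital sign by the dominant frequency of their
coefficient series (largest non-DC FFT peak, 4x zero-padded): respiration
if it falls in 0.1–0.5 Hz, heartbeat if in 0.8–2 Hz. At most `max_k = 4`
components per band are kept, in descending-eigenvalue order, and weighted
by eigenvalue share

    w_i = lambda_i / sum_{j in kept} lambda_j,

so the reconstruction `sum_i w_i q_i y_i(t)` (returned to a 1-D series by
anti-diagonal averaging, mean not re-added) emphasises the strongest
in-band structure. Uniform weights `1/K` recover the plain-PCA baseline
and are exposed as a comparison mode. An absolute eigenvalue interval can
additionally gate the selection; such thresholds are hardware- and
scale-specific, so the scale-free band rule is the default and the
interval is off unless configured.

## MUSIC frequency estimation

Each reconstructed branch is cut into unit-hop snapshots of length
`N = 32`; the snapshot covariance (forward averaging, `(1/L) X X^H`) is
eigendecomposed and split into signal and noise subspaces. The signal
dimension is chosen by MDL (AIC optional), clamped to `[2, N-2]` and
rounded up to even (real tones occupy conjugate exponential pairs).
Eigenvalues are floored at `max * 1e-12` before the information criteria:
numerically-zero eigenvalues otherwise destabilise the geometric-mean
term and inflate the estimated order on noiseless inputs.

The pseudo-spectrum

    P(omega) = 1 / (a(omega)^H U_N U_N^H a(omega)),
    a(omega) = [1, e^{-j omega}, ..., e^{-j (N-1) omega}]^T

is evaluated on 1024 grid points across the branch's physiological band
(digital frequency `omega = 2*pi*f/fs`; restricting to the positive-
frequency band keeps the mirrored peak of the real input out of the
search). The estimate is the global argmax (lowest frequency on ties) and
the rate is `round(60*f)` BPM, rounding half away from zero (0.29 Hz →
17 BPM, 1.35 Hz → 81 BPM). A fixed signal dimension of 2 per branch was
evaluated and rejected: when a residual harmonic accompanies the branch
tone, the top-2 eigenvectors mix both tones and the peak lands between
them, whereas MDL expands the signal subspace so that both tones peak and
the stronger (true) tone wins.

## Synthetic data

The simulator generates one chirp per slow-time frame (the pipeline uses
one phase sample per frame; intra-frame chirp averaging is available as an
optional noise-reduction flag). Frame `k`, ADC sample `n`:

    x[k, n] = exp(j*(2*pi*f_b*n/fs_adc + 4*pi*R(t_k)/lambda)) + clutter + DC + noise

with `R(t_k) = R_0 + d(t_k)` and a deterministic displacement
`d(t)` summing the respiration and heartbeat fundamentals and their
declared harmonics. Defaults emulate a seated adult at 1 m: 0.29 Hz /
5 mm respiration with 2nd and 3rd harmonics at 15% and 5%, 1.35 Hz /
0.35 mm heartbeat with a 20% 2nd harmonic, two static clutter reflectors
(0.5 m and 1.8 m at amplitudes 0.3 and 0.2 relative to the chest echo), a
0.1+0.1j DC offset, and complex Gaussian noise at 10 dB SNR relative to
the mean noiseless power. Radar defaults: 60.25 GHz carrier, 3.6 GHz
bandwidth, 64 µs chirp, 128 ADC points at 2 MHz, 20 Hz frame rate, 60 s
observation. A single seeded generator drives the noise (and optional
phase noise); nothing else consumes randomness.

What the simulator does **not** emulate: body motion artefacts, multipath,
multiple subjects, radar nonidealities (nonlinear chirps, IQ imbalance),
or the non-stationarity of real breathing. Passing tests therefore
demonstrate correctness of the algorithmic chain under the stated model,
not field performance on human subjects.

## Numerical choices

- Covariance normalisation `1/L` (not `1/(L-1)`); orthonormality asserted
  to 1e-10, covariance reconstruction to 1e-8.
- Eigenvector signs fixed by the largest-component-positive rule; argmax
  ties break to the lowest index/frequency everywhere.
- Pseudo-spectrum denominators are floored so values cap at 1e300; capped
  grid points are flagged.
- Embedding window `M = 100` samples (5 s at 20 Hz, spanning more than one
  respiration cycle); snapshot length `N = 32`; search grid 1024 points.
- Degenerate (all-constant) decomposition inputs return zero eigenvalues
  with an identity basis and a warning; zero-amplitude cubes propagate to
  an explicit "no physiological component" error.

## Evaluation metrics

For a batch of seeded trials the detection error is

    Er = |Mv - Rv| / Rv * 100,      accuracy = 100 - Er,

with `Mv` and `Rv` the totals of measured and reference rates over all
trials; reference rates are the integer BPM a reference monitor reports.
Per-trial errors, the standard deviation and the variance of the estimates
are reported alongside, since totals can hide compensating errors. The
bundled evaluation uses 20 trials of 60 s at 10 dB SNR — a desk-scale
analogue of a human study, sized so the entire suite runs in seconds.

## Known limitations

- The Hankel-embedding interpretation of the separation stage is this
  package's own well-posed construction; other multivariate inputs
  (multi-bin range data, multi-chirp stacks) would also fit the same
  weighted-PCA framework.
- The published absolute eigenvalue intervals for component selection are
  tied to their authors' data scale; here they are optional configuration.
- MUSIC assumes quasi-stationary tones over the observation window; rate
  changes within the window bias the estimate toward the dominant rate.
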