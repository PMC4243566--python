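"""Statistical inference over a hidden inter-spike-interval process.

A two-input neuron watches spike pairs whose hidden ISI drifts from -20 to
0 steps and whose jitter then ramps up.  After every presentation the
frozen receptive field is probed: its argmax is the neuron's ISI estimate,
its boundaries the tolerated range, and the output pulse width reads out
the current noise level.
"""
import numpy as np

from skan import run_tracking

n = 300
mu = np.concatenate([np.linspace(-20, 0, 100), np.zeros(n - 100)])
sigma = np.concatenate([np.zeros(150), np.linspace(0, 3, n - 150)])
df = run_tracking(mu, sigma, seed=2)

cols = ["presentation", "mu", "sigma", "observed_isi", "rf_argmax",
        "rf_lo", "rf_hi", "pulse_width"]
print(df.iloc[[0, 30, 60, 99, 150, 220, 299]][cols].to_string(index=False))

ok = df.dropna(subset=["rf_argmax"])
track = ok[ok.presentation >= 30]
print(f"\nmean |estimate - hidden mu| after presentation 30: "
      f"{(track.rf_argmax - track.mu).abs().mean():.2f} dt")
quiet = df[(df.presentation >= 100) & (df.presentation < 150)]
noisy = df[df.presentation >= 270]
print(f"mean pulse width, jitter 0: {quiet[quiet.pulse_width > 0].pulse_width.mean():.2f} dt; "
      f"jitter ~3 dt: {noisy[noisy.pulse_width > 0].pulse_width.mean():.2f} dt "
      f"(width reads out noise)")
print(f"missed presentations at high jitter: "
      f"{(noisy.pulse_width == 0).mean():.0%} (ISI outside the receptive field)")
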