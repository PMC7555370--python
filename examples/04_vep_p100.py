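"""Flash-VEP averaging and P100 extraction, with baseline normalization.

Simulates two sessions of 120 flash trials on the occipital leads — a
pre-insult baseline (P100 10 µV at 100 ms) and a post-insult session with an
attenuated, delayed P100 (4 µV at 115 ms) — then recovers both and expresses
the second relative to the first, the usual way evoked potentials are
reported after asphyxia.
"""

from neoqeeg.syngen import gen_vep_recording
from neoqeeg.vep import average_trials, extract_trials, normalize_vep, p100_metrics


def session(amplitude, latency, seed):
    recording, triggers, _ = gen_vep_recording(
        120, p100_amplitude_uv=amplitude, p100_latency_ms=latency,
        noise_sd_uv=20.0, seed=seed)
    trials = extract_trials(recording, triggers, leads=("O1", "O2"))
    return p100_metrics(average_trials(trials))


baseline = session(10.0, 100.0, seed=10)
followup = session(4.0, 115.0, seed=11)
followup = normalize_vep(followup, baseline)

print(f"baseline : P100 {baseline.p100_amplitude_uv:.1f} uV "
      f"at {baseline.p100_latency_ms:.1f} ms ({baseline.n_trials} trials)")
print(f"follow-up: P100 {followup.p100_amplitude_uv:.1f} uV "
      f"at {followup.p100_latency_ms:.1f} ms")
print(f"normalized amplitude {followup.normalized_amplitude:.2f} "
      f"(attenuation to {100 * followup.normalized_amplitude:.0f}% of baseline), "
      f"normalized latency {followup.normalized_latency:.2f}")
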