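"""Inspect the empirical null and its FDR threshold curve.

Builds the N(a, m) table from a peak-free simulation and prints m_min(a):
the smallest IP read count that is significant in a window carrying a
total of `a` reads. The enforced column is non-decreasing by construction;
dips in the raw column (sampling noise at rare amplitudes) are flattened
by the max-with-previous sweep.
"""

from dipseq import (
    DipConfig,
    SimConfig,
    build_null_table,
    compute_min_magnitude,
    normalize_tracks,
    scan_segments,
    simulate_tracks,
)

sim = SimConfig(seed=7)  # 1 Mb, 1e5 reads/track, shared background only
ip, control, _ = simulate_tracks(sim)
config = DipConfig(seed=7)

ip, control = normalize_tracks(ip, control, config.seed)
segments = scan_segments(ip, control, sim.genome(), config)
null = build_null_table(segments)
thresholds = compute_min_magnitude(null, config.phi)

frame = thresholds.to_frame()
print(f"{null.n_segments} segments, amplitudes 0..{thresholds.amax}, phi={config.phi}")
print(frame.iloc[::5].to_string(index=False))
print("\nreading: in a window with amplitude a, at least m_min_enforced of the")
print("reads must come from the IP track before the window is called significant")
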