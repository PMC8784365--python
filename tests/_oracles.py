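"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own interval algebra and pooling
logic: group similarity by an explicit double loop over all vector pairs,
and efficiency by sampling the timeline on a 1 ms grid.
"""

import numpy as np


def brute_force_group_similarity(target, pool):
    """(mean_expert, mean_novice, diff) by explicit looping with self-exclusion."""
    expert_sims, novice_sims = [], []
    for other in pool:
        if other.participant_id == target.participant_id:
            continue
        if target.level == "segment" and other.segment_type != target.segment_type:
            continue
        sim = sum(a * b for a, b in zip(target.components, other.components))
        if other.group == "expert":
            expert_sims.append(sim)
        else:
            novice_sims.append(sim)
    me = sum(expert_sims) / len(expert_sims)
    mn = sum(novice_sims) / len(novice_sims)
    return me, mn, me - mn


def _productive_at(intervals, t):
    for iv in intervals:
        if iv.start_s <= t < iv.end_s:
            return iv.label.is_productive
    return False


def sampled_segment_efficiency(segment, dt=0.001):
    """(s_eff_left, s_eff_right, b_eff, T) by counting 1 ms grid midpoints."""
    start, end = segment.start_s, segment.end_s
    n = max(int(round((end - start) / dt)), 1)
    times = start + (np.arange(n) + 0.5) * dt
    left = np.array([_productive_at(segment.intervals_left, t) for t in times])
    right = np.array([_productive_at(segment.intervals_right, t) for t in times])
    T = end - start
    return (
        float(left.mean()),
        float(right.mean()),
        float((left & right).mean()),
        T,
    )


def sampled_suture_efficiency(suture, dt=0.001):
    """Duration-weighted aggregate of the sampled per-segment efficiencies."""
    total = prod_l = prod_r = both = 0.0
    for seg in suture.segments:
        sl, sr, b, T = sampled_segment_efficiency(seg, dt)
        total += T
        prod_l += sl * T
        prod_r += sr * T
        both += b * T
    return prod_l / total, prod_r / total, both / total, total
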