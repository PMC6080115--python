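"""Independent straight-line reimplementation of the whole pairing pipeline.

Deliberately naive (linear scans, no numpy, hard-coded thresholds) so it
shares no code path with the package; used as the oracle in equivalence
tests on small fixtures.  Operates on plain tuples:

* diary rows:  (participant_id, sensor_id, time, recorded_code)
* trace samples: {sensor_id: [(time, value), ...]} sorted by time
* events: [(participant_id, time), ...]
"""

THRESHOLDS = {"DG5": [1.0, 2.0, 3.0], "FL": [1.0, 2.0]}


class Excluded(Exception):
    def __init__(self, reason):
        super().__init__(reason)
        self.reason = reason


def classify(rate, system):
    mag = 0
    for th in THRESHOLDS[system]:
        if abs(rate) > th:
            mag += 1
    if rate > 0:
        return mag
    if rate < 0:
        return -mag
    return 0


def interp(samples, t, max_gap):
    if t < samples[0][0] or t > samples[-1][0]:
        raise Excluded("out-of-range")
    for (t0, v0), (t1, v1) in zip(samples, samples[1:]):
        if t == t0:
            return v0
        if t0 < t < t1:
            if t1 - t0 > max_gap:
                raise Excluded("gap")
            return v0 + (v1 - v0) * (t - t0) / (t1 - t0)
    return samples[-1][1]  # t == last sample time


def analyze(diary_rows, trace_samples, events, system,
            horizon=30.0, max_gap=float("inf"), pre=30.0, post=120.0):
    """Returns (result rows, exclusion rows).

    Result rows: (recorded, calculated, diff, in_window); exclusions:
    (sensor_id, time, reason).
    """
    results, excluded = [], []
    for pid, sid, t, rec in diary_rows:
        samples = trace_samples[sid]
        try:
            g0 = interp(samples, t, max_gap)
            g1 = interp(samples, t + horizon, max_gap)
        except Excluded as e:
            excluded.append((sid, t, e.reason))
            continue
        calc = classify((g1 - g0) / horizon, system)
        inw = any(et - pre < t < et + post for ep, et in events if ep == pid)
        results.append((rec, calc, abs(rec - calc), inw))
    return results, excluded


def tabulate(results):
    """Pooled counts: (n, match, off1, off2plus, n_inside)."""
    n = len(results)
    match = sum(1 for r in results if r[2] == 0)
    off1 = sum(1 for r in results if r[2] == 1)
    off2 = sum(1 for r in results if r[2] >= 2)
    inside = sum(1 for r in results if r[3])
    return n, match, off1, off2, inside


def pair_agreement(diary_rows):
    """Brute-force parallel-sensor agreement: diffs over (pid, time) pairs."""
    groups = {}
    for pid, sid, t, rec in diary_rows:
        groups.setdefault((pid, t), []).append(rec)
    diffs, unpaired = [], 0
    for recs in groups.values():
        if len(recs) == 2:
            diffs.append(abs(recs[0] - recs[1]))
        else:
            unpaired += len(recs)
    return diffs, unpaired
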