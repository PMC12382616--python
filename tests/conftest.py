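import numpy as np
import pytest

import rewardmap as rm
from rewardmap.synthetic import make_phantom


@pytest.fixture(scope="session")
def design():
    return rm.generate_task_design(seed=11)


@pytest.fixture(scope="session")
def records(design):
    return rm.simulate_agent_bets(
        design, rm.AgentPolicy(miss_rate=0.02, risk_shift_after_loss=0.2),
        seed=12)


@pytest.fixture(scope="session")
def phantom():
    return rm.default_phantom()


@pytest.fixture(scope="session")
def phantom_volumes(phantom):
    return make_phantom(phantom)


def jaccard(a, b):
    a, b = set(map(tuple, a)), set(map(tuple, b))
    return len(a & b) / len(a | b) if a | b else 0.0


def brute_force_scores(recs):
    """Exhaustive-window behavioral scorer re-examining every window."""
    n = len(recs)
    out = {k: 0 for k in (
        "bet50_prv1loss", "bet10_prv1loss", "bet50_prv2loss", "bet10_prv2loss",
        "bet50_prv3loss", "bet10_prv3loss", "bet50_prv2netloss",
        "bet10_prv2netloss", "bet50_prv3netloss", "bet10_prv3netloss")}
    for t in range(n):
        for k in (1, 2, 3):
            if t >= k and all(recs[t - j].outcome == "loss" for j in range(1, k + 1)):
                if recs[t].bet == 50:
                    out[f"bet50_prv{k}loss"] += 1
                if recs[t].bet == 10:
                    out[f"bet10_prv{k}loss"] += 1
        for k in (2, 3):
            if t >= k and sum(recs[t - j].delta for j in range(1, k + 1)) < 0:
                if recs[t].bet == 50:
                    out[f"bet50_prv{k}netloss"] += 1
                if recs[t].bet == 10:
                    out[f"bet10_prv{k}netloss"] += 1
    out["net_outcome"] = sum(r.delta for r in recs)
    return out


def random_records(rng, n=240, p_miss=0.1):
    """Random trial sequences (wins/losses/missed, 10/50 bets)."""
    recs = []
    for i in range(n):
        u = rng.random()
        if u < p_miss:
            bet, outcome, delta = "missed", "missed", 0
        else:
            bet = 50 if rng.random() < 0.5 else 10
            outcome = "win" if rng.random() < 0.5 else "loss"
            delta = bet if outcome == "win" else -bet
        recs.append(rm.TrialRecord(
            index=i + 1, pie_chance=0.5, bet=bet, outcome=outcome,
            delta=delta, cue_onset_s=i * 2.5, feedback_onset_s=i * 2.5 + 1.5))
    return recs


def flood_fill_components(volume, connectivity):
    """Brute-force BFS connected components of a boolean 3D field."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(volume.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(volume)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < volume.shape[i] for i in range(3)) \
                        and volume[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)
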