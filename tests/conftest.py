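"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles —
flat rescans, closed-form linear-algebra solutions — so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from cysbond.repertoire_core import Chain, CloneRecord, RepertoireSample

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_cysteine_index(
    sample: RepertoireSample, min_count: int = 3, trbv1_min_length: int = 8
):
    """Independent recount of the cysteine index by direct rescanning.

    Re-implements every rule with plain loops: drop clones seen fewer than
    ``min_count`` times, drop beta TRBV1 clones with CDR3 shorter than
    ``trbv1_min_length``, then count clones with a Cys within 2 positions
    of the apex (largest position <= n/2 + 1), each clone once.  Returns
    (index_percent, n_eligible, n_apex_cys) or None when nothing is
    eligible.
    """
    eligible = []
    for clone in sample.clones:
        if clone.detection_count < min_count:
            continue
        if (
            clone.chain is Chain.beta
            and clone.v_gene.upper() == "TRBV1"
            and len(clone.cdr3_aa) < trbv1_min_length
        ):
            continue
        eligible.append(clone)
    if not eligible:
        return None
    n_cys = 0
    for clone in eligible:
        n = len(clone.cdr3_aa)
        apex = max(p for p in range(1, n + 1) if p <= n / 2 + 1)
        hit = any(
            clone.cdr3_aa[p - 1] == "C" and abs(p - apex) <= 2
            for p in range(1, n + 1)
        )
        n_cys += hit
    if n_cys == 0:
        return 100.0 / len(eligible), len(eligible), 0
    return 100.0 * n_cys / len(eligible), len(eligible), n_cys


def random_clone(rng: np.random.Generator, cys_rate: float = 0.15) -> CloneRecord:
    """A random clone for oracle-equivalence fixtures (TRBV1-enriched)."""
    length = int(rng.integers(4, 17))
    residues = [AA[i] for i in rng.integers(0, len(AA), size=length)]
    for i in range(length):
        if rng.random() < cys_rate:
            residues[i] = "C"
    cdr3 = "".join(residues)
    v_gene = "TRBV1" if rng.random() < 0.3 else f"TRBV{int(rng.integers(2, 30))}"
    junction = "C" + cdr3 + "F"
    nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3 * len(junction)))
    return CloneRecord(
        v_gene=v_gene,
        chain=Chain.beta,
        cdr3_nt=nt,
        junction_aa=junction,
        cdr3_aa=cdr3,
        detection_count=int(rng.integers(1, 9)),
        productive=True,
    )


def random_sample(rng: np.random.Generator, max_clones: int = 50) -> RepertoireSample:
    n = int(rng.integers(1, max_clones + 1))
    clones: dict[tuple, CloneRecord] = {}
    while len(clones) < n:
        c = random_clone(rng)
        clones[c.key] = c
    return RepertoireSample(
        sample_id=f"fixture-{rng.integers(1e6)}",
        clones=list(clones.values()),
        chain=Chain.beta,
    )


def closed_form_states(params, concentration: float, y0, t):
    """Matrix-exponential solution of the two-state affine ODE.

    Builds the augmented homogeneous system for x' = A x + b and evaluates
    expm(M t) @ (y0, 1); returns the (noncovalent, covalent) trajectories.
    """
    a = params.kon * concentration
    M = np.array(
        [
            [-(a + params.koff + params.kcov), -a, a * params.rmax],
            [params.kcov, 0.0, 0.0],
            [0.0, 0.0, 0.0],
        ]
    )
    z0 = np.array([y0[0], y0[1], 1.0])
    out = np.empty((len(t), 2))
    for i, ti in enumerate(np.asarray(t, dtype=float)):
        out[i] = (expm(M * ti) @ z0)[:2]
    return out


def closed_form_at(params, schedule, times):
    """Piecewise closed-form response evaluated at given absolute times."""
    segments = list(schedule.segments)
    if schedule.dissociation_duration > 0:
        segments.append((0.0, schedule.dissociation_duration))
    bounds = np.cumsum([0.0] + [d for _, d in segments])
    y = np.zeros(2)
    out = np.empty(len(times))
    times = np.asarray(times, dtype=float)
    for i, (conc, dur) in enumerate(segments):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        if i > 0:  # boundary points belong to the earlier segment
            mask &= times > lo
        local = times[mask] - lo
        if local.size:
            out[mask] = closed_form_states(params, conc, y, local).sum(axis=1)
        y = closed_form_states(params, conc, y, [dur])[0]
    return out


def closed_form_sensorgram(params, schedule, t_points_per_segment: int = 50):
    """Piecewise closed-form sensorgram over an injection schedule."""
    segments = list(schedule.segments)
    if schedule.dissociation_duration > 0:
        segments.append((0.0, schedule.dissociation_duration))
    y = np.zeros(2)
    times, traj = [], []
    t0 = 0.0
    for conc, dur in segments:
        t = np.linspace(0.0, dur, t_points_per_segment)
        states = closed_form_states(params, conc, y, t)
        times.append(t + t0)
        traj.append(states)
        y = states[-1]
        t0 += dur
    return np.concatenate(times), np.vstack(traj)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
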