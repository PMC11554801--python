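import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import wcyears as w

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_cohort():
    """Complete synthetic cohort, 1500 participants, fixed seed."""
    cfg = w.SimConfig(n_participants=1500, seed=11)
    return cfg, w.generate_cohort(cfg)


@pytest.fixture(scope="session")
def landmark_rows(small_cohort):
    """All-cancer landmark rows built on the truth exposures (no
    trajectory-model noise), split by sex."""
    _, cohort = small_cohort
    tx = cohort.truth["true_exposures"]
    rows = w.assemble_landmark_dataset(cohort, tx, "all")
    return {
        sex: rows[rows["sex"] == sex].reset_index(drop=True)
        for sex in ("male", "female")
    }


def brute_force_concordance(times, events, scores):
    """Exhaustive-pair Harrell C with the standard tie conventions.

    Usable pairs: distinct times where the shorter-time member has the
    event; tied times with exactly one event (the event member is the
    earlier); tied times with two events are not comparable.  Tied scores
    count 1/2.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    s = np.asarray(scores, float)
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, ei, ej, si, sj = t[i], t[j], e[i], e[j], s[i], s[j]
            if ti > tj or (ti == tj and not ei and ej):
                ti, tj, ei, ej, si, sj = tj, ti, ej, ei, sj, si
            if ti < tj:
                if not ei:
                    continue
            else:  # tied times
                if ei and ej:
                    continue  # not comparable
                if not ei:
                    continue
            den += 1
            if si > sj:
                num += 1.0
            elif si == sj:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


@pytest.fixture(scope="session")
def brute_c():
    return brute_force_concordance
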