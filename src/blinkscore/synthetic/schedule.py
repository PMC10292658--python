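"""Trial schedules for delay eyeblink conditioning sessions.

Each session comprises 22 blocks of 10 trials: 9 paired CS-US trials and
1 CS-only trial per block, in a seeded pseudorandom position, separated by
inter-trial intervals of at least 12 s.
"""
from __future__ import annotations

import numpy as np

from ..types import CS_ONLY, PAIRED, US_ONSET_MS, TrialSchedule, TrialSpec

BLOCKS_PER_SESSION = 22
TRIALS_PER_BLOCK = 10
PAIRED_PER_BLOCK = 9
MIN_ITI_S = 12.0
#: Mean of the exponential tail added to the 12 s ITI floor. The protocol
#: states only the lower bound; 12 + Exp(3) s keeps the median near 14 s.
ITI_EXTRA_MEAN_S = 3.0


def generate_schedule(n_sessions: int, seed: int) -> list[TrialSchedule]:
    """Generate ``n_sessions`` seeded training-session schedules.

    Parameters
    ----------
    n_sessions : int
        Number of daily sessions (the full protocol uses 12).
    seed : int
        Seed for the pseudorandom CS-only placement and the ITI draws.

    Returns
    -------
    list of TrialSchedule
        One schedule per session, each with 22 blocks of 10 trials
        (9 paired + 1 CS-only), every ITI >= 12 s. Deterministic in ``seed``.
    """
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    rng = np.random.default_rng(seed)
    schedules = []
    for s in range(1, n_sessions + 1):
        trials: list[TrialSpec] = []
        for _ in range(BLOCKS_PER_SESSION):
            cs_only_pos = int(rng.integers(TRIALS_PER_BLOCK))
            itis = MIN_ITI_S + rng.exponential(ITI_EXTRA_MEAN_S, TRIALS_PER_BLOCK)
            for pos in range(TRIALS_PER_BLOCK):
                if pos == cs_only_pos:
                    trials.append(
                        TrialSpec(CS_ONLY, cs_onset_ms=0.0, iti_s=float(itis[pos]))
                    )
                else:
                    trials.append(
                        TrialSpec(
                            PAIRED,
                            cs_onset_ms=0.0,
                            us_onset_ms=US_ONSET_MS,
                            iti_s=float(itis[pos]),
                        )
                    )
        schedules.append(TrialSchedule(session_index=s, trials=tuple(trials)))
    return schedules
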