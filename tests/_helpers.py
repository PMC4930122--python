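"""Shared helpers for building small hand-specified sessions."""

import numpy as np

from twostep.agents import Session


def make_session(a1, is_common, s2, a2, r, valid=None):
    n = len(a1)
    t = np.arange(n, dtype=float)
    return Session(
        a1=np.array(a1), is_common=np.array(is_common), s2=np.array(s2),
        a2=np.array(a2), reward=np.array(r),
        valid=np.array(valid) if valid is not None else np.ones(n, dtype=np.int64),
        onset1=10.0 * t, onset2=10.0 * t + 3.5, onset_fb=10.0 * t + 5.5,
    )
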