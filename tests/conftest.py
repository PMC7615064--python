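"""Shared fixtures: crafted session logs with exact, hand-controllable
statistics, used by scoring and QC tests."""
from __future__ import annotations

import pytest

from cogbat.config import SstConfig, VmacConfig
from cogbat.session import SessionLog, SstTrialRecord, VmacTrialRecord


def make_sst_log(go_rts, stop_responded, ssds, go_errors=0, go_omissions=0):
    """Build an SST session log with exact trial-level statistics.

    go_rts: RTs of responded-correct go trials; go_errors/go_omissions add
    wrong-side and no-response go trials; stop_responded is a list of bools
    (True = failed stop) paired with ssds.
    """
    trials = []
    i = 0
    for rt in go_rts:
        trials.append(SstTrialRecord(i, False, "go", "left", "left",
                                     int(rt), None, None, 10))
        i += 1
    for _ in range(go_errors):
        trials.append(SstTrialRecord(i, False, "go", "left", "right",
                                     500, None, None, 0))
        i += 1
    for _ in range(go_omissions):
        trials.append(SstTrialRecord(i, False, "go", "left", "none",
                                     None, None, None, 0))
        i += 1
    for responded, ssd in zip(stop_responded, ssds):
        trials.append(SstTrialRecord(
            i, False, "stop", "left",
            "left" if responded else "none",
            500 if responded else None, int(ssd), not responded, 0,
        ))
        i += 1
    return SessionLog(task="sst", config=SstConfig(), seed=0, trials=trials)


def make_vmac_log(cell_rts, n_errors=None, config=None):
    """Build a VMAC log from per-cell correct RT lists.

    cell_rts maps (phase, color) -> list of correct RTs; n_errors maps the
    same keys to a count of incorrect trials to append.
    """
    config = config or VmacConfig()
    n_errors = n_errors or {}
    trials = []
    i = 0
    for (phase, color), rts in cell_rts.items():
        if color == "none":
            value = "absent"
        else:
            high_now = (color == config.high_color) == (phase == "training")
            value = "high" if high_now else "low"
        block = 1 if phase == "training" else config.n_blocks_training + 1
        for rt in rts:
            trials.append(VmacTrialRecord(i, block, phase, value, color,
                                          "left", "left", int(rt), True, 10))
            i += 1
        for _ in range(n_errors.get((phase, color), 0)):
            trials.append(VmacTrialRecord(i, block, phase, value, color,
                                          "left", "right", 500, False, 0))
            i += 1
    return SessionLog(task="vmac", config=config, seed=0, trials=trials)


@pytest.fixture
def sst_integration_fixture():
    """Four go RTs {400,500,600,700}, half the stop trials failed, mean SSD
    300: integration rank 2 -> 500 -> SSRT 200; mean method 550-300=250."""
    return make_sst_log(
        go_rts=[400, 500, 600, 700],
        stop_responded=[True, False, True, False],
        ssds=[250, 300, 300, 350],
    )
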