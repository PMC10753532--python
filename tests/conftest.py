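"""Shared fixtures and independent reference implementations.

The brute-force QC reference here deliberately re-derives the two validity
criteria from first principles (full-stream scans, no searchsorted, no
index bookkeeping) so it can serve as an oracle for the production
implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from msikit.formats_io import PositionLog, RawRun, Scan
from msikit.simulator import make_phantom_config, simulate_run


# ---------------------------------------------------------------------------
# Independent brute-force QC reference
# ---------------------------------------------------------------------------


def brute_force_qc(run: RawRun, log: PositionLog, mode: str, tol_ppm: float):
    """Verdict-for-verdict reference for the MS2 validity filter."""
    window = {"parallel": 2, "sequential": 1}[mode]
    out = []
    for i, scan in enumerate(run.scans):
        if scan.ms_level != 2:
            continue
        laser = any(on <= scan.time_s < off for on, off in log.laser_intervals)
        following_ms1 = [
            j for j in range(i + 1, len(run.scans)) if run.scans[j].ms_level == 1
        ][:window]
        if len(following_ms1) < window:
            consistent = False
        else:
            consistent = all(
                any(
                    abs(mz - scan.precursor_mz) <= scan.precursor_mz * tol_ppm * 1e-6
                    for mz in run.scans[j].mz
                )
                for j in following_ms1
            )
        out.append((i, laser, consistent))
    return out


# ---------------------------------------------------------------------------
# Random scan-stream generator (edge-case rich, not simulator-based)
# ---------------------------------------------------------------------------


def random_run(rng: np.random.Generator, max_scans: int = 200):
    """A randomized scan stream plus laser log for oracle-equivalence tests.

    Includes MS2 scans at the very end of the run, laser intervals with
    gaps, precursors that drift in and out of tolerance, and empty MS1
    scans.
    """
    n_scans = int(rng.integers(5, max_scans + 1))
    base_mzs = rng.uniform(160.0, 880.0, size=8)
    scans = []
    t = 0.0
    for i in range(n_scans):
        t += float(rng.uniform(0.05, 0.4))
        is_ms2 = rng.random() < 0.4 and i > 0
        if is_ms2:
            precursor = float(rng.choice(base_mzs))
            # drift sometimes inside, sometimes outside a few-ppm tolerance
            precursor *= 1.0 + float(rng.normal(0, 4e-6))
            scans.append(
                Scan(
                    index=i,
                    time_s=t,
                    ms_level=2,
                    mz=np.sort(rng.uniform(150.0, precursor, size=3)),
                    intensity=rng.uniform(1.0, 100.0, size=3),
                    precursor_mz=precursor,
                    isolation_width=1.0,
                )
            )
        else:
            present = base_mzs[rng.random(base_mzs.size) < 0.7]
            jittered = np.sort(present * (1.0 + rng.normal(0, 2e-6, size=present.size)))
            scans.append(
                Scan(
                    index=i,
                    time_s=t,
                    ms_level=1,
                    mz=jittered,
                    intensity=rng.uniform(100.0, 1e4, size=jittered.size),
                )
            )
    total = t + 0.5
    edges = np.sort(rng.uniform(0.0, total, size=4))
    log = PositionLog(
        lines=[(0, 0.0, total, 0.0)],
        laser_intervals=[(float(edges[0]), float(edges[1])), (float(edges[2]), float(edges[3]))],
    )
    run = RawRun(scans=scans, polarity="positive", mass_range=(100.0, 1000.0))
    return run, log


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic phantom run shared across tests."""
    config = make_phantom_config(n_lines=8, n_cols=10, n_compounds=5, seed=11)
    run, log, truth = simulate_run(config)
    return config, run, log, truth


@pytest.fixture(scope="session")
def parallel_sim():
    config = make_phantom_config(
        n_lines=10, n_cols=12, n_compounds=8, mode="parallel", seed=7
    )
    run, log, truth = simulate_run(config)
    return config, run, log, truth
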