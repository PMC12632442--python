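"""Shared fixtures and scenario builders."""

from __future__ import annotations

import numpy as np
import pytest

import headturnkit as htk


def pulse_signal(
    amplitude: float,
    peak_velocity: float,
    fs: float = 100.0,
    n_subpeaks: int = 1,
    pad_s: float = 10.0,
) -> tuple[np.ndarray, int]:
    """A single scripted pulse embedded in zeros; returns (yaw, onset index)."""
    p = htk.make_turn_profile(amplitude, peak_velocity, n_subpeaks, fs)
    pad = int(pad_s * fs)
    yaw = np.zeros(2 * pad + p.size)
    yaw[pad : pad + p.size] = p
    return yaw, pad


def free_living_scripts(
    rng: np.random.Generator,
    n_turns: int,
    gap_s: float = 2.0,
    start_s: float = 10.0,
    amp_range: tuple[float, float] = (20.0, 90.0),
    vel_ratio_range: tuple[float, float] = (1.5, 2.5),
    coupling_choices: tuple[float, ...] = (0.0, 1.0),
) -> list[htk.TurnScript]:
    """Scripted head turns with kinematics in the free-living range
    (amplitudes 20-90 deg, peak velocity 1.5-2.5 x amplitude per second,
    alternating directions, gaps >= ``gap_s``)."""
    scripts = []
    t = start_s
    for i in range(n_turns):
        amp = float(rng.uniform(*amp_range))
        vel = amp * float(rng.uniform(*vel_ratio_range))
        sign = 1 if rng.random() < 0.5 else -1
        coupling = float(rng.choice(coupling_choices))
        scripts.append(
            htk.TurnScript(
                onset_time=t,
                amplitude=sign * amp,
                peak_velocity=vel,
                segment_coupling=coupling,
            )
        )
        t += 2.0 * amp / vel + gap_s + float(rng.uniform(0, 1))
    return scripts


def turn_scenario(
    seed: int,
    n_turns: int = 20,
    gyro_noise_sd: float = 1.0,
    duration_h: float | None = None,
    **script_kwargs,
):
    """A head-turn scenario plus its ground truth."""
    rng = np.random.default_rng(seed)
    scripts = free_living_scripts(rng, n_turns, **script_kwargs)
    last_end = scripts[-1].onset_time + 2 * abs(
        scripts[-1].amplitude
    ) / scripts[-1].peak_velocity
    dur_h = duration_h if duration_h is not None else (last_end + 10.0) / 3600.0
    cfg = htk.ScenarioConfig(
        duration_h=dur_h,
        turn_scripts={"head": scripts},
        gyro_noise_sd=gyro_noise_sd,
        accel_noise_sd=0.01,
        seed=seed,
    )
    return htk.simulate_recording(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
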