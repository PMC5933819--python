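"""Random-dot-motion stimulus parameters and dot kinematics.

The perceptual task shows ~300 dots in a 3-degree circular aperture; a fixed
proportion (the coherence) steps in a common direction each frame while the
rest step in independent random directions.  Dots live for a fixed number of
frames and are respawned uniformly in the aperture.  Ten difficulty levels
span coherences 51.2% (easiest) to 1.6% (hardest) on a log ladder; the
control stimulus is 100% coherent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RDMParams", "coherence_for_level", "generate_rdm_frames", "CONTROL_LEVEL"]

#: reserved level code for the 100%-coherence control stimulus
CONTROL_LEVEL = 0

_COH_MAX = 51.2  # percent, level 1
_COH_MIN = 1.6   # percent, level 10
_N_LEVELS = 10

_DIRECTIONS = {
    "right": 0.0,
    "up": np.pi / 2,
    "left": np.pi,
    "down": -np.pi / 2,
}


@dataclass(frozen=True)
class RDMParams:
    coherence: float  # percent in (0, 100]
    direction: str = "right"
    n_dots: int = 300
    dot_radius: float = 0.08  # degrees; recorded "density: 2.0%" is metadata only
    aperture_radius: float = 3.0  # degrees
    speed: float = 8.0  # degrees / s
    lifetime: int = 3  # frames
    frame_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.coherence <= 100:
            raise ValueError("coherence must be in (0, 100]")
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.lifetime < 1:
            raise ValueError("lifetime must be >= 1 frame")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(_DIRECTIONS)}")


def coherence_for_level(level: int) -> float:
    """Coherence (percent) for a difficulty level; level 0 is the control.

    Levels 1..10 are log-spaced from 51.2% down to 1.6%.
    """
    if level == CONTROL_LEVEL:
        return 100.0
    if not 1 <= level <= _N_LEVELS:
        raise ValueError(f"level must be in [1, {_N_LEVELS}] or {CONTROL_LEVEL}")
    ratio = (_COH_MIN / _COH_MAX) ** ((level - 1) / (_N_LEVELS - 1))
    return _COH_MAX * ratio


def generate_rdm_frames(
    params: RDMParams,
    n_frames: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate dot positions for ``n_frames`` frames.

    Returns ``(positions, coherent)`` where ``positions`` has shape
    ``(n_frames, n_dots, 2)`` (degrees, aperture-centred) and ``coherent`` is
    a boolean flag per dot.  ``round(coherence/100 * n_dots)`` dots step
    ``speed / frame_rate`` degrees in the common direction every frame; the
    rest step the same distance in independent uniform-random directions.
    Dots older than ``lifetime`` frames respawn uniformly in the aperture,
    and dots that exit re-enter on the opposite side (wrap-around).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    n = params.n_dots
    n_coh = int(round(params.coherence / 100.0 * n))
    coherent = np.zeros(n, dtype=bool)
    coherent[:n_coh] = True
    step = params.speed / params.frame_rate
    theta = _DIRECTIONS[params.direction]
    coh_step = step * np.array([np.cos(theta), np.sin(theta)])
    R = params.aperture_radius

    def spawn(k: int) -> np.ndarray:
        # uniform in the disc
        r = R * np.sqrt(rng.uniform(size=k))
        phi = rng.uniform(0, 2 * np.pi, size=k)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    pos = spawn(n)
    age = rng.integers(0, params.lifetime, size=n)  # staggered initial ages
    frames = np.empty((n_frames, n, 2))
    frames[0] = pos
    for f in range(1, n_frames):
        age += 1
        expired = age >= params.lifetime
        pos[expired] = spawn(int(expired.sum()))
        age[expired] = 0
        alive = ~expired
        move = np.zeros((n, 2))
        move[coherent & alive] = coh_step
        rnd = (~coherent) & alive
        phi = rng.uniform(0, 2 * np.pi, size=int(rnd.sum()))
        move[rnd] = step * np.column_stack([np.cos(phi), np.sin(phi)])
        pos = pos + move
        # wrap-around re-entry through the centre for dots leaving the disc
        out = np.hypot(pos[:, 0], pos[:, 1]) > R
        pos[out] = -pos[out] * (2 * R / np.hypot(pos[out, 0], pos[out, 1]) - 1)[:, None]
        frames[f] = pos
    return frames, coherent
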