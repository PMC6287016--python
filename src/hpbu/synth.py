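"""Synthetic single-stroke handwriting corpus.

Stands in for a tablet-recorded digit corpus: each digit 0-9 has a
hand-designed single-stroke template (ordered control points in a
roughly 0.6 x 1 canvas box, pen-up strokes avoided by using cursive
one-stroke forms where needed) with a nominal writing duration.
Exemplars are produced by jittering the template's stroke geometry and
timing and interpolating a smooth pen path:

* each control-point displacement is rotated by N(0, angle_sd^2)
  radians and scaled by (1 + N(0, scale_sd^2)) — angle noise is
  zero-mean, so exemplar headings are unbiased around the template;
* per-segment durations (proportional to segment length) are jittered
  by (1 + N(0, timing_sd^2));
* the pen path is monotone cubic (PCHIP) interpolation of x(t) and
  y(t) through the timed control points, sampled at ``sample_rate``;
  the interpolant slows naturally into and out of turns, giving a
  bell-shaped speed profile within segments.

Generation is deterministic per seed; corpus assembly derives one child
seed per exemplar from a master seed and records everything in a
manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .trajectory import Trajectory, read_trajectory, write_trajectory

__all__ = [
    "DigitTemplate",
    "NoiseLevels",
    "CorpusSpec",
    "Corpus",
    "digit_template",
    "generate_digit",
    "generate_corpus",
    "save_corpus",
    "load_corpus",
]

MANIFEST_VERSION = "hpbu-corpus-1"

# Control points are (x, y) with y up; durations in seconds chosen for
# plausible handwriting speed (strokes of ~2-4 canvas units of path in
# ~1 s at unit digit height).
_TEMPLATE_POINTS = {
    0: [(0.28, 0.95), (0.16, 0.90), (0.09, 0.72), (0.09, 0.50), (0.09, 0.28),
        (0.16, 0.10), (0.29, 0.05), (0.43, 0.10), (0.50, 0.28), (0.50, 0.50),
        (0.50, 0.72), (0.43, 0.90), (0.30, 0.95)],
    1: [(0.16, 0.70), (0.26, 0.88), (0.32, 1.00), (0.32, 0.66), (0.32, 0.33),
        (0.32, 0.00)],
    2: [(0.10, 0.80), (0.18, 0.95), (0.33, 1.00), (0.48, 0.92), (0.52, 0.75),
        (0.42, 0.55), (0.25, 0.35), (0.10, 0.12), (0.05, 0.00), (0.30, 0.00),
        (0.55, 0.00)],
    3: [(0.08, 0.92), (0.25, 1.00), (0.45, 0.92), (0.50, 0.75), (0.38, 0.58),
        (0.22, 0.52), (0.38, 0.46), (0.52, 0.30), (0.46, 0.10), (0.28, 0.00),
        (0.08, 0.06)],
    4: [(0.40, 1.00), (0.26, 0.70), (0.10, 0.42), (0.30, 0.42), (0.52, 0.42),
        (0.47, 0.75), (0.47, 0.40), (0.47, 0.00)],
    5: [(0.50, 1.00), (0.30, 1.00), (0.12, 1.00), (0.10, 0.78), (0.10, 0.58),
        (0.30, 0.62), (0.47, 0.50), (0.50, 0.28), (0.40, 0.08), (0.20, 0.00),
        (0.06, 0.10)],
    6: [(0.50, 1.00), (0.35, 0.85), (0.20, 0.60), (0.10, 0.35), (0.12, 0.12),
        (0.30, 0.00), (0.48, 0.12), (0.50, 0.32), (0.35, 0.45), (0.18, 0.38)],
    7: [(0.06, 0.93), (0.30, 1.00), (0.55, 0.97), (0.42, 0.60), (0.30, 0.30),
        (0.22, 0.00)],
    8: [(0.44, 0.90), (0.30, 1.00), (0.15, 0.90), (0.14, 0.72), (0.30, 0.57),
        (0.46, 0.42), (0.50, 0.22), (0.36, 0.02), (0.18, 0.05), (0.12, 0.25),
        (0.28, 0.45), (0.45, 0.62), (0.46, 0.82), (0.33, 0.97)],
    9: [(0.50, 0.90), (0.35, 1.00), (0.16, 0.90), (0.12, 0.70), (0.20, 0.52),
        (0.38, 0.50), (0.50, 0.62), (0.52, 0.85), (0.52, 0.55), (0.50, 0.28),
        (0.46, 0.00)],
}

_TEMPLATE_DURATION = {
    0: 1.1, 1: 0.8, 2: 1.2, 3: 1.3, 4: 1.1,
    5: 1.2, 6: 1.1, 7: 0.9, 8: 1.5, 9: 1.2,
}


@dataclass(frozen=True)
class DigitTemplate:
    digit: int
    control_points: np.ndarray  # (k, 2)
    duration: float             # s
    sample_rate: float = 100.0  # Hz

    def __post_init__(self):
        pts = np.asarray(self.control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
            raise ValueError("template needs >= 4 planar control points")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        pts.setflags(write=False)
        object.__setattr__(self, "control_points", pts)


def digit_template(digit: int, sample_rate: float = 100.0) -> DigitTemplate:
    if digit not in _TEMPLATE_POINTS:
        raise KeyError(f"no template for digit {digit}")
    return DigitTemplate(
        digit=digit,
        control_points=np.array(_TEMPLATE_POINTS[digit], dtype=float),
        duration=_TEMPLATE_DURATION[digit],
        sample_rate=sample_rate,
    )


@dataclass(frozen=True)
class NoiseLevels:
    """Exemplar-to-exemplar variability (all standard deviations)."""

    angle_sd: float = 0.04   # rad, rotation of each control displacement
    scale_sd: float = 0.04   # relative length jitter per displacement
    timing_sd: float = 0.06  # relative per-segment duration jitter

    @classmethod
    def none(cls) -> "NoiseLevels":
        return cls(0.0, 0.0, 0.0)


def _rotate(v: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def generate_digit(
    template: DigitTemplate,
    seed: int,
    noise: NoiseLevels = NoiseLevels(),
) -> Trajectory:
    """One noisy exemplar of a digit template, deterministic per seed."""
    rng = np.random.default_rng(seed)
    pts = template.control_points
    disp = np.diff(pts, axis=0)
    n_seg = disp.shape[0]

    thetas = rng.normal(0.0, noise.angle_sd, n_seg) if noise.angle_sd > 0 else np.zeros(n_seg)
    scales = 1.0 + (rng.normal(0.0, noise.scale_sd, n_seg) if noise.scale_sd > 0 else np.zeros(n_seg))
    scales = np.maximum(scales, 0.1)
    jit_disp = np.array([_rotate(d, th) * s for d, th, s in zip(disp, thetas, scales)])
    jit_pts = np.vstack([pts[:1], pts[0] + np.cumsum(jit_disp, axis=0)])

    seg_len = np.maximum(np.hypot(*jit_disp.T), 1e-9)
    seg_dur = template.duration * seg_len / seg_len.sum()
    tim = 1.0 + (rng.normal(0.0, noise.timing_sd, n_seg) if noise.timing_sd > 0 else np.zeros(n_seg))
    seg_dur = seg_dur * np.maximum(tim, 0.2)
    t_knots = np.concatenate([[0.0], np.cumsum(seg_dur)])

    fx = PchipInterpolator(t_knots, jit_pts[:, 0])
    fy = PchipInterpolator(t_knots, jit_pts[:, 1])
    n = int(np.floor(t_knots[-1] * template.sample_rate)) + 1
    t = np.arange(n) / template.sample_rate
    return Trajectory(t, np.column_stack([fx(t), fy(t)]))


@dataclass(frozen=True)
class CorpusSpec:
    """What to generate: which digits, how many exemplars, how noisy."""

    digits: tuple = tuple(range(10))
    n_per_digit: int = 10
    noise: NoiseLevels = NoiseLevels()
    master_seed: int = 0
    sample_rate: float = 100.0
    exclude: tuple = ()

    def __post_init__(self):
        digits = tuple(d for d in self.digits if d not in set(self.exclude))
        if not digits:
            raise ValueError("corpus digit set is empty")
        if self.n_per_digit < 1:
            raise ValueError("n_per_digit must be >= 1")
        object.__setattr__(self, "digits", digits)


def exemplar_seed(master_seed: int, digit: int, index: int) -> int:
    """Child seed for one exemplar; a simple counter keeps it < 2^31."""
    return (int(master_seed) * 1009 + digit * 101 + index) % (2**31 - 1)


@dataclass
class Corpus:
    """Labelled exemplar trajectories plus their generation record."""

    spec: CorpusSpec
    items: list = field(default_factory=list)  # (digit, seed, Trajectory)

    def __len__(self) -> int:
        return len(self.items)

    def trajectories(self):
        for digit, seed, traj in self.items:
            yield digit, seed, traj


def generate_corpus(spec: CorpusSpec) -> Corpus:
    corpus = Corpus(spec=spec)
    for digit in spec.digits:
        template = digit_template(digit, spec.sample_rate)
        for k in range(spec.n_per_digit):
            seed = exemplar_seed(spec.master_seed, digit, k)
            corpus.items.append((digit, seed, generate_digit(template, seed, spec.noise)))
    return corpus


def save_corpus(corpus: Corpus, out_dir) -> Path:
    """One CSV per exemplar plus ``manifest.json``; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": MANIFEST_VERSION,
        "master_seed": corpus.spec.master_seed,
        "n_per_digit": corpus.spec.n_per_digit,
        "noise": {
            "angle_sd": corpus.spec.noise.angle_sd,
            "scale_sd": corpus.spec.noise.scale_sd,
            "timing_sd": corpus.spec.noise.timing_sd,
        },
        "sample_rate": corpus.spec.sample_rate,
        "files": [],
    }
    for i, (digit, seed, traj) in enumerate(corpus.items):
        name = f"digit{digit}_ex{i % corpus.spec.n_per_digit:02d}.csv"
        write_trajectory(traj, out_dir / name)
        manifest["files"].append({"file": name, "digit": digit, "seed": seed})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_corpus(corpus_dir) -> Corpus:
    corpus_dir = Path(corpus_dir)
    manifest = json.loads((corpus_dir / "manifest.json").read_text())
    if manifest.get("format") != MANIFEST_VERSION:
        raise ValueError(f"unrecognised corpus manifest format: {manifest.get('format')}")
    noise = NoiseLevels(**manifest["noise"])
    digits = tuple(sorted({f["digit"] for f in manifest["files"]}))
    spec = CorpusSpec(
        digits=digits,
        n_per_digit=manifest["n_per_digit"],
        noise=noise,
        master_seed=manifest["master_seed"],
        sample_rate=manifest["sample_rate"],
    )
    corpus = Corpus(spec=spec)
    for entry in manifest["files"]:
        traj = read_trajectory(corpus_dir / entry["file"])
        corpus.items.append((entry["digit"], entry["seed"], traj))
    return corpus
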