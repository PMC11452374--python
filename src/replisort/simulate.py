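"""Synthetic fluorescence scenes with ground truth.

Generates multi-channel nuclear images that emulate what the analysis
pipeline sees at the microscope: disk-shaped nuclei in a DNA channel,
phase-specific replication-foci (RF) patterns, and a second foci channel
(TF, e.g. transcription) whose ground-truth colocalized fraction with the
RF foci is controlled by ``coloc_fraction_phi``.  Foci are isotropic
Gaussian spots; every channel is blurred with a Gaussian PSF and corrupted
with Poisson photon noise over signal plus background and additive Gaussian
read noise.  A fixed seed fully determines the scene, with one RNG
sub-stream per nucleus so adding nuclei does not perturb earlier ones.

The per-phase focus archetypes follow the qualitative microscopy phenotypes:
early-S nuclei show sparse, dim foci in the interior (euchromatin); middle-S
nuclei dense, brighter foci; late-S nuclei few large, bright foci biased
toward the nuclear rim (heterochromatin); G1/G2 nuclei show none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ChannelImage, CountMask

#: Base focus peak amplitude (photon counts) that "1x" refers to.
BASE_FOCUS_AMPLITUDE = 300.0

DEFAULT_PHASE_MIX = {"G1G2": 0.25, "EARLY": 0.25, "MIDDLE": 0.25, "LATE": 0.25}


@dataclass
class FociParams:
    """Archetype of one phase's replication-foci pattern."""

    n_foci: int
    focus_sigma_px: float
    focus_amplitude: float


def phase_archetype_defaults(phase: str) -> FociParams:
    """Default focus pattern per cell-cycle group.

    Chosen so that the default sorting thresholds separate the archetypes:
    MIDDLE is far denser than EARLY, and LATE is sparser, brighter and
    larger-spotted than EARLY while staying below the middle-density
    threshold.
    """
    table = {
        "G1G2": FociParams(0, 1.5, 0.0),
        "EARLY": FociParams(15, 1.5, 1.0 * BASE_FOCUS_AMPLITUDE),
        "MIDDLE": FociParams(120, 1.5, 2.0 * BASE_FOCUS_AMPLITUDE),
        "LATE": FociParams(6, 2.0, 6.0 * BASE_FOCUS_AMPLITUDE),
    }
    if phase not in table:
        raise ValueError(f"unknown phase {phase!r}")
    return table[phase]


@dataclass
class SceneSpec:
    """Full description of one synthetic scene (the seed pins everything)."""

    n_nuclei: int = 60
    nucleus_radius_mean: float = 24.0
    nucleus_radius_sd: float = 2.0
    phase_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHASE_MIX))
    foci_params: dict[str, FociParams] | None = None
    tf_n_foci: int = 40
    tf_focus_sigma_px: float = 1.5
    tf_focus_amplitude: float = BASE_FOCUS_AMPLITUDE
    coloc_fraction_phi: float | dict[str, float] = 0.5
    psf_sigma_px: float = 1.0
    gaussian_sd: float = 2.0
    poisson: bool = True
    background_level: float = 100.0
    dna_amplitude: float = 300.0
    shape: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be ≥ 1")
        total = sum(self.phase_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phase_mix proportions must sum to 1")
        phis = (self.coloc_fraction_phi.values()
                if isinstance(self.coloc_fraction_phi, dict)
                else [self.coloc_fraction_phi])
        if any(not 0 <= p <= 1 for p in phis):
            raise ValueError("coloc_fraction_phi must lie in [0, 1]")

    def phi_for(self, phase: str) -> float:
        if isinstance(self.coloc_fraction_phi, dict):
            return self.coloc_fraction_phi.get(phase, 0.0)
        return self.coloc_fraction_phi

    def foci_for(self, phase: str) -> FociParams:
        if self.foci_params and phase in self.foci_params:
            return self.foci_params[phase]
        return phase_archetype_defaults(phase)


@dataclass
class NucleusTruth:
    """Ground truth of one simulated nucleus."""

    label: int
    phase: str
    center: tuple[float, float]
    radius: float
    rf_foci: np.ndarray  # (n, 2) row/col coordinates
    tf_foci: np.ndarray
    coincident_tf_indices: np.ndarray  # indices into tf_foci placed on RF foci


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth]

    def phase_of(self, label: int) -> str:
        for nuc in self.nuclei:
            if nuc.label == label:
                return nuc.phase
        raise KeyError(label)


def _default_shape(spec: SceneSpec) -> tuple[int, int]:
    r = spec.nucleus_radius_mean + 3 * spec.nucleus_radius_sd
    area = spec.n_nuclei * np.pi * r**2 / 0.3  # ~30% packing
    side = int(np.ceil(np.sqrt(area)))
    side = max(side, int(4 * r))
    return side, side


def _place_nuclei(spec: SceneSpec, shape, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centres and radii."""
    centres, radii = [], []
    h, w = shape
    for i in range(spec.n_nuclei):
        placed = False
        for _ in range(500):
            r = max(8.0, rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd))
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 2) ** 2
                   for (y, x), rr in zip(centres, radii)):
                centres.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place nuclei without overlap; use fewer or smaller "
                "nuclei, or a larger scene")
    return centres, radii


def _sample_foci(
    n: int, centre, radius, rng: np.random.Generator, rim_bias: bool
) -> np.ndarray:
    """Focus centres inside a disk; optionally biased toward the rim."""
    if n == 0:
        return np.empty((0, 2))
    u = rng.uniform(size=n)
    # uniform disk: r ∝ sqrt(u); rim-biased (heterochromatin-like): r ∝ u^(1/4).
    # Sampling runs to the full radius: confining foci to an inner disk would
    # imprint a shared dark rim on both channels and fake positive
    # cross-correlation between independent patterns.
    rad = (u ** (0.25 if rim_bias else 0.5)) * radius
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack(
        [centre[0] + rad * np.sin(theta), centre[1] + rad * np.cos(theta)]
    )


def _render_spots(shape, coords: np.ndarray, sigma: float, amplitude: float) -> np.ndarray:
    img = np.zeros(shape)
    if len(coords) == 0 or amplitude == 0:
        return img
    half = int(np.ceil(4 * sigma))
    for cy, cx in coords:
        y0 = max(0, int(np.floor(cy)) - half)
        y1 = min(shape[0], int(np.floor(cy)) + half + 1)
        x0 = max(0, int(np.floor(cx)) - half)
        x1 = min(shape[1], int(np.floor(cx)) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return img


def _detect(signal_img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """PSF blur, then photon (Poisson) and read (Gaussian) noise plus background."""
    img = signal_img
    if spec.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_px)
    img = img + spec.background_level
    if spec.poisson:
        img = rng.poisson(img).astype(float)
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_scene(
    spec: SceneSpec,
) -> tuple[ChannelImage, ChannelImage, ChannelImage, CountMask, GroundTruth]:
    """Render one scene: DNA, RF and TF channels, truth mask, ground truth.

    TF foci: per nucleus, ``round(phi * min(n_rf_foci, tf_n_foci))`` are
    placed exactly on RF focus coordinates; the remainder uniformly within
    the nucleus.
    """
    shape = spec.shape or _default_shape(spec)
    root = np.random.SeedSequence(spec.seed)
    place_seq, noise_seq, *nuc_seqs = root.spawn(2 + spec.n_nuclei)
    place_rng = np.random.default_rng(place_seq)

    centres, radii = _place_nuclei(spec, shape, place_rng)

    # assign phases deterministically by proportion, then shuffle
    phases: list[str] = []
    order = ["G1G2", "EARLY", "MIDDLE", "LATE"]
    counts = {p: int(np.floor(spec.phase_mix.get(p, 0.0) * spec.n_nuclei)) for p in order}
    while sum(counts.values()) < spec.n_nuclei:
        # distribute remainders by largest fractional part
        fracs = {p: spec.phase_mix.get(p, 0.0) * spec.n_nuclei - counts[p] for p in order}
        counts[max(fracs, key=fracs.get)] += 1
    for p in order:
        phases.extend([p] * counts[p])
    place_rng.shuffle(phases)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dna_signal = np.zeros(shape)
    rf_signal = np.zeros(shape)
    tf_signal = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    nuclei_truth: list[NucleusTruth] = []

    for i, (centre, radius, phase) in enumerate(zip(centres, radii, phases)):
        label = i + 1
        rng = np.random.default_rng(nuc_seqs[i])
        disk = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2
        labels[disk] = label
        dna_signal[disk] = spec.dna_amplitude

        fp = spec.foci_for(phase)
        rim = phase in ("MIDDLE", "LATE")
        rf_coords = _sample_foci(fp.n_foci, centre, radius, rng, rim_bias=rim)
        rf_signal += _render_spots(shape, rf_coords, fp.focus_sigma_px, fp.focus_amplitude)

        phi = spec.phi_for(phase)
        n_tf = spec.tf_n_foci
        n_coinc = int(round(phi * min(len(rf_coords), n_tf))) if len(rf_coords) else 0
        coinc_idx = np.arange(n_coinc)
        if n_coinc > 0:
            pick = rng.choice(len(rf_coords), size=n_coinc, replace=False)
            tf_coords = rf_coords[pick]
        else:
            tf_coords = np.empty((0, 2))
        free = _sample_foci(n_tf - n_coinc, centre, radius, rng, rim_bias=False)
        tf_coords = np.vstack([tf_coords, free])
        tf_signal += _render_spots(
            shape, tf_coords, spec.tf_focus_sigma_px, spec.tf_focus_amplitude
        )

        nuclei_truth.append(
            NucleusTruth(label, phase, tuple(centre), float(radius),
                         rf_coords, tf_coords, coinc_idx)
        )

    noise_rng = np.random.default_rng(noise_seq)
    dna = _detect(dna_signal, spec, noise_rng)
    rf = _detect(rf_signal, spec, noise_rng)
    tf = _detect(tf_signal, spec, noise_rng)

    frame = f"scene-{spec.seed}"
    return (
        ChannelImage(dna, channel_role="DNA", frame_id=frame),
        ChannelImage(rf, channel_role="RF", frame_id=frame),
        ChannelImage(tf, channel_role="TF", frame_id=frame),
        CountMask(labels),
        GroundTruth(nuclei_truth),
    )


def generate_coloc_nucleus(
    n_foci: int = 200,
    phi: float = 0.5,
    radius: float = 40.0,
    focus_sigma_px: float = 1.5,
    amplitude: float = BASE_FOCUS_AMPLITUDE,
    psf_sigma_px: float = 1.0,
    noise: bool = True,
    background_level: float = 100.0,
    gaussian_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One disk nucleus with two foci channels at ground-truth fraction phi.

    Returns ``(channel_a, channel_b, mask)``; ``round(phi * n_foci)`` foci of
    channel b coincide with channel-a foci, the rest are independent and
    uniform in the disk.  The workhorse fixture for ICCS calibration tests.
    """
    pad = 12
    side = int(2 * (radius + pad))
    shape = (side, side)
    centre = (side / 2, side / 2)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    mask = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2

    a_coords = _sample_foci(n_foci, centre, radius, rng, rim_bias=False)
    n_coinc = int(round(phi * n_foci))
    pick = rng.choice(n_foci, size=n_coinc, replace=False) if n_coinc else []
    b_coords = np.vstack(
        [a_coords[pick] if n_coinc else np.empty((0, 2)),
         _sample_foci(n_foci - n_coinc, centre, radius, rng, rim_bias=False)]
    )

    spec = SceneSpec(
        n_nuclei=1,
        psf_sigma_px=psf_sigma_px,
        poisson=noise,
        gaussian_sd=gaussian_sd if noise else 0.0,
        background_level=background_level,
    )
    a = _render_spots(shape, a_coords, focus_sigma_px, amplitude)
    b = _render_spots(shape, b_coords, focus_sigma_px, amplitude)
    a = _detect(a, spec, rng)
    b = _detect(b, spec, rng)
    return a, b, mask
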