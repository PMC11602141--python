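"""Synthetic two-channel kymograph generator.

Emulates the single-molecule stretched-DNA assay: a ~38 kb DNA tethered at
both ends, imaged at 10 Hz in a DNA (intercalator) channel and a ParB
channel. Plectonemes appear as diffusing high-intensity spots carrying a
fixed total of plectonemic DNA; ParB dimers load at the *parS* site,
diffuse along the DNA and dissociate after a delayed-dissociation dwell
time. A "pinned" condensation scenario collapses all plectonemic DNA into
a single static, growing spot with ParB accumulated on it.

The generator produces ground-truth tracks (for validating detection,
linking, sizing, diffusion and classification) and renders them into
kymographs with a Gaussian PSF and a Poisson + Gaussian camera model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .kinetics import ResidenceModel, sample_residence_time
from .preprocess import Kymograph

__all__ = [
    "SimConfig",
    "CondensationScenario",
    "GroundTruthTrack",
    "dimer_label_fraction",
    "brownian_track",
    "simulate_tracks",
    "render_kymograph",
    "simulate_kymographs",
]


def dimer_label_fraction(label_eff_monomer: float) -> float:
    """Fraction of dimers carrying at least one fluorophore.

    Each monomer is labeled independently with probability ``e``, so a
    dimer is visible unless both labels are missing: ``1 - (1 - e)**2``.
    At the measured 74% monomer efficiency this gives 93% visible dimers.
    """
    e = float(label_eff_monomer)
    if not (0.0 <= e <= 1.0):
        raise ValueError("labeling efficiency must be in [0, 1]")
    return 1.0 - (1.0 - e) ** 2


@dataclass
class CondensationScenario:
    """Optional condensation of all plectonemic DNA at one pinned site.

    In ``pinned`` mode, from ``onset_frame`` onward every plectoneme is
    replaced by a single zero-drift condensate at ``pin_rel_pos`` whose DNA
    content ramps linearly from ``start_kb`` to ``end_kb`` (defaults mirror
    the observed ~40% growth of the condensed cluster, ~8 -> ~11.5 kb).
    ``n_parb_bound`` stationary labeled ParB dimers mark the condensate in
    the protein channel.
    """

    mode: str = "off"  # "off" | "pinned"
    pin_rel_pos: float = 0.4
    onset_frame: int = 200
    start_kb: float = 8.0
    end_kb: float = 11.5
    n_parb_bound: int = 8


@dataclass
class SimConfig:
    """Study conditions for the synthetic assay.

    Defaults correspond to the experimental geometry: a 38 kb molecule
    with *parS* at relative position 0.4, 10 Hz imaging, ~12 kb of
    plectonemic DNA (|sigma| ~ 0.05), ParB diffusion ~0.69 kb^2/s and
    delayed-dissociation rates (0.017, 0.047) s^-1 as on positively
    supercoiled DNA, and 74% monomer labeling efficiency.
    """

    dna_length_kb: float = 38.0
    pars_rel_pos: float = 0.4
    n_pixels: int = 100
    margin_px: int = 12  # empty pixels rendered beyond each tether end
    frame_interval_s: float = 0.1
    n_frames: int = 600
    plectonemic_dna_kb: float = 12.0
    n_plectonemes_mean: float = 2.0
    plectoneme_mode: str = "fixed"  # "fixed" | "birth-death"
    plectoneme_turnover_per_s: float = 0.1
    d_plectoneme_kb2s: float = 20.0
    d_parb_kb2s: float = 0.69
    parb_load_rate_per_s: float = 0.05
    label_eff_monomer: float = 0.74
    residence_model: ResidenceModel = field(
        default_factory=lambda: ResidenceModel(0.017, 0.047))
    psf_sigma_px: float = 1.0
    photon_scale: float = 50.0  # DNA-channel photons per kb per frame
    parb_photons: float = 200.0  # photons per labeled dimer per frame
    background_level: float = 20.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True  # False renders the expected (noise-free) image
    condensation: CondensationScenario = field(default_factory=CondensationScenario)
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.pars_rel_pos < 1.0):
            raise ValueError("pars_rel_pos must lie strictly inside (0, 1)")
        if self.plectonemic_dna_kb > self.dna_length_kb:
            raise ValueError("plectonemic DNA cannot exceed the molecule length")
        if self.n_pixels < 4:
            raise ValueError("n_pixels must be >= 4")
        if self.margin_px < 0:
            raise ValueError("margin_px must be nonnegative")
        for name in ("dna_length_kb", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("plectonemic_dna_kb", "n_plectonemes_mean",
                     "d_plectoneme_kb2s", "d_parb_kb2s", "parb_load_rate_per_s",
                     "psf_sigma_px", "photon_scale", "parb_photons",
                     "background_level", "read_noise_sd",
                     "plectoneme_turnover_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.label_eff_monomer <= 1.0):
            raise ValueError("label_eff_monomer must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.plectoneme_mode not in ("fixed", "birth-death"):
            raise ValueError("plectoneme_mode must be 'fixed' or 'birth-death'")
        if self.condensation.mode not in ("off", "pinned"):
            raise ValueError("condensation mode must be 'off' or 'pinned'")

    @property
    def kb_per_pixel(self) -> float:
        return self.dna_length_kb / self.n_pixels

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthTrack:
    """One simulated moving feature over the half-open frame interval
    ``[birth_frame, death_frame)``.

    ``positions_kb`` and ``size_kb`` have one entry per live frame;
    ``size_kb`` is DNA content for plectonemes/condensates and 0 for ParB
    dimers. ``labeled`` is meaningful only for ParB (None otherwise).
    """

    kind: str  # "plectoneme" | "parb_dimer" | "condensate"
    birth_frame: int
    death_frame: int
    positions_kb: np.ndarray
    size_kb: np.ndarray
    labeled: bool | None = None

    def __post_init__(self) -> None:
        self.positions_kb = np.asarray(self.positions_kb, dtype=float)
        self.size_kb = np.asarray(self.size_kb, dtype=float)
        n = self.death_frame - self.birth_frame
        if n <= 0:
            raise ValueError("death_frame must exceed birth_frame")
        if self.positions_kb.shape != (n,) or self.size_kb.shape != (n,):
            raise ValueError("per-frame arrays must match the track lifetime")
        if np.any(self.size_kb < 0):
            raise ValueError("size_kb must be nonnegative")


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold positions into [0, length] (reflecting boundaries)."""
    period = 2.0 * length
    x = np.mod(x, period)
    return np.where(x > length, period - x, x)


def brownian_track(
    d_kb2s: float,
    n_frames: int,
    frame_interval_s: float,
    rng: np.random.Generator,
    start_kb: float = 0.0,
    length_kb: float | None = None,
) -> np.ndarray:
    """1-D Brownian trajectory in kb; reflected into [0, length_kb] if given."""
    steps = rng.normal(0.0, np.sqrt(2.0 * d_kb2s * frame_interval_s), size=n_frames - 1)
    x = start_kb + np.concatenate([[0.0], np.cumsum(steps)])
    if length_kb is not None:
        x = _reflect(x, length_kb)
    return x


def _simulate_plectonemes(config: SimConfig, rng, last_frame: int) -> list[GroundTruthTrack]:
    """Plectoneme tracks on frames [0, last_frame)."""
    total = config.plectonemic_dna_kb
    if total <= 0 or last_frame <= 0:
        return []
    L = config.dna_length_kb
    dt = config.frame_interval_s

    if config.plectoneme_mode == "fixed":
        k = max(1, int(round(config.n_plectonemes_mean)))
        sizes = rng.dirichlet(np.ones(k)) * total
        tracks = []
        for i in range(k):
            pos = brownian_track(config.d_plectoneme_kb2s, last_frame, dt, rng,
                                 start_kb=rng.uniform(0.0, L), length_kb=L)
            tracks.append(GroundTruthTrack(
                kind="plectoneme", birth_frame=0, death_frame=last_frame,
                positions_kb=pos, size_kb=np.full(last_frame, sizes[i])))
        return tracks

    # birth-death mode: deaths at the turnover rate, births keep the mean;
    # the partition of the total plectonemic DNA is redrawn on every change
    # so that conservation holds exactly at every frame.
    mu = config.plectoneme_turnover_per_s
    lam = mu * config.n_plectonemes_mean
    alive: list[dict] = []
    records: list[dict] = []

    def spawn(frame: int) -> None:
        alive.append({"birth": frame, "pos": [rng.uniform(0.0, L)], "sizes": []})

    def repartition() -> None:
        if alive:
            parts = rng.dirichlet(np.ones(len(alive))) * total
            for tr, s in zip(alive, parts):
                tr["share"] = s

    k0 = max(1, rng.poisson(config.n_plectonemes_mean))
    for _ in range(k0):
        spawn(0)
    repartition()
    step_sd = np.sqrt(2.0 * config.d_plectoneme_kb2s * dt)
    for f in range(last_frame):
        changed = False
        survivors = []
        for tr in alive:
            if f > tr["birth"] and rng.random() < mu * dt:
                records.append(tr)
                changed = True
            else:
                survivors.append(tr)
        alive[:] = survivors
        for _ in range(rng.poisson(lam * dt)):
            spawn(f)
            changed = True
        if not alive:
            spawn(f)
            changed = True
        if changed:
            repartition()
        for tr in alive:
            if f > tr["birth"]:
                nxt = _reflect(np.array([tr["pos"][-1] + rng.normal(0.0, step_sd)]), L)
                tr["pos"].append(float(nxt[0]))
            tr["sizes"].append(tr["share"])
    records.extend(alive)
    tracks = []
    for tr in records:
        n = len(tr["sizes"])
        if n == 0:
            continue
        tracks.append(GroundTruthTrack(
            kind="plectoneme", birth_frame=tr["birth"], death_frame=tr["birth"] + n,
            positions_kb=np.asarray(tr["pos"][:n]), size_kb=np.asarray(tr["sizes"])))
    return tracks


def simulate_tracks(config: SimConfig, rng: np.random.Generator) -> list[GroundTruthTrack]:
    """Simulate ground-truth plectoneme, ParB and condensate tracks.

    Plectonemes partition ``plectonemic_dna_kb`` and diffuse with reflecting
    boundaries; ParB dimers load at *parS* as a Poisson process, diffuse,
    and live for a delayed-dissociation dwell; in the pinned scenario all
    plectonemic DNA collapses into one static growing condensate carrying
    stationary ParB.
    """
    config.validate()
    L = config.dna_length_kb
    dt = config.frame_interval_s
    n_frames = config.n_frames
    scen = config.condensation
    pinned = scen.mode == "pinned"
    plect_end = min(scen.onset_frame, n_frames) if pinned else n_frames

    tracks = _simulate_plectonemes(config, rng, plect_end)

    if pinned and scen.onset_frame < n_frames:
        n = n_frames - scen.onset_frame
        ramp = np.linspace(scen.start_kb, scen.end_kb, n)
        pin = scen.pin_rel_pos * L
        tracks.append(GroundTruthTrack(
            kind="condensate", birth_frame=scen.onset_frame, death_frame=n_frames,
            positions_kb=np.full(n, pin), size_kb=ramp))
        p_vis = dimer_label_fraction(config.label_eff_monomer)
        for _ in range(scen.n_parb_bound):
            tracks.append(GroundTruthTrack(
                kind="parb_dimer", birth_frame=scen.onset_frame, death_frame=n_frames,
                positions_kb=np.full(n, pin), size_kb=np.zeros(n),
                labeled=bool(rng.random() < p_vis)))

    # freely diffusing ParB dimers loading at parS
    p_vis = dimer_label_fraction(config.label_eff_monomer)
    pars = config.pars_rel_pos * L
    for f in range(n_frames):
        for _ in range(rng.poisson(config.parb_load_rate_per_s * dt)):
            dwell = sample_residence_time(config.residence_model, rng)
            death = min(n_frames, f + max(1, int(round(dwell / dt))))
            n = death - f
            pos = brownian_track(config.d_parb_kb2s, n, dt, rng,
                                 start_kb=pars, length_kb=L)
            tracks.append(GroundTruthTrack(
                kind="parb_dimer", birth_frame=f, death_frame=death,
                positions_kb=pos, size_kb=np.zeros(n),
                labeled=bool(rng.random() < p_vis)))
    return tracks


def _deposit(profile: np.ndarray, pos_px: float, amount: float) -> None:
    """Add ``amount`` at a sub-pixel position by linear interpolation."""
    n = profile.size
    i = int(np.floor(pos_px))
    frac = pos_px - i
    i = min(max(i, 0), n - 1)
    j = min(i + 1, n - 1)
    profile[i] += amount * (1.0 - frac)
    profile[j] += amount * frac


def render_kymograph(
    tracks: list[GroundTruthTrack],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[Kymograph, Kymograph]:
    """Render ground-truth tracks into (DNA, ParB) kymographs.

    DNA channel: the non-plectonemic DNA forms a uniform baseline across
    the tether span and each plectoneme/condensate deposits its DNA content
    at its position; the expected photon count is ``kb * photon_scale``
    after Gaussian PSF blurring (reflective ends, flux-conserving). ParB
    channel: each *labeled* dimer deposits ``parb_photons``. Camera model:
    Poisson shot noise on the expected signal, plus a constant background
    offset, plus Gaussian read noise.
    """
    config.validate()
    n_px = config.n_pixels
    margin = config.margin_px
    width = n_px + 2 * margin
    n_frames = config.n_frames
    kbpx = config.kb_per_pixel
    L = config.dna_length_kb

    dna_exp = np.zeros((n_frames, width))
    parb_exp = np.zeros((n_frames, width))

    loop_kb = np.zeros(n_frames)  # DNA sequestered in plectonemes per frame
    for tr in tracks:
        if tr.kind in ("plectoneme", "condensate"):
            loop_kb[tr.birth_frame:tr.death_frame] += tr.size_kb
    baseline = (L - loop_kb) / n_px  # kb per pixel of stretched backbone
    dna_exp[:, margin:margin + n_px] += baseline[:, None]

    for tr in tracks:
        px = tr.positions_kb / kbpx + margin
        if np.any(tr.positions_kb < -1e-9) or np.any(tr.positions_kb > L + 1e-9):
            raise ValueError("track positions exceed the molecule span")
        if tr.kind in ("plectoneme", "condensate"):
            for k, f in enumerate(range(tr.birth_frame, tr.death_frame)):
                _deposit(dna_exp[f], px[k], tr.size_kb[k])
        elif tr.kind == "parb_dimer" and tr.labeled:
            for k, f in enumerate(range(tr.birth_frame, tr.death_frame)):
                _deposit(parb_exp[f], px[k], 1.0)

    dna_exp *= config.photon_scale
    parb_exp *= config.parb_photons
    if config.psf_sigma_px > 0:
        # constant mode: signal blurring past the tether ends lands in the
        # margins, as in a real image; total expected flux is conserved
        dna_exp = gaussian_filter1d(dna_exp, config.psf_sigma_px, axis=1, mode="constant")
        parb_exp = gaussian_filter1d(parb_exp, config.psf_sigma_px, axis=1, mode="constant")

    def camera(expected: np.ndarray) -> np.ndarray:
        if config.shot_noise and expected.max() > 0:
            img = rng.poisson(expected).astype(float)
        else:
            img = expected.copy()
        img += config.background_level
        if config.read_noise_sd > 0:
            img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
        return img

    meta = dict(frame_interval_s=config.frame_interval_s, kb_per_pixel=kbpx,
                end_pixels=(margin, margin + n_px - 1))
    dna = Kymograph(intensity=camera(dna_exp), channel="dna", **meta)
    parb = Kymograph(intensity=camera(parb_exp), channel="parb", **meta)
    return dna, parb


def simulate_kymographs(config: SimConfig, rng: np.random.Generator | None = None):
    """Convenience wrapper: simulate tracks and render both channels.

    Returns ``(tracks, dna_kymo, parb_kymo)``; deterministic for a fixed
    ``config.rng_seed`` when ``rng`` is omitted.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    tracks = simulate_tracks(config, rng)
    dna, parb = render_kymograph(tracks, config, rng)
    return tracks, dna, parb
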