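"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator emulates one input class of the analysis pipeline and returns,
next to the data, a :class:`SimTruth` record of everything that was planted:
track identities and mobility classes, condensate centers, blob masks and
areas, hub age classes, FRAP parameters, motif positions and strong-contact
labels.  All generators are deterministic given their seed.

Modelling choices: molecules bound inside a condensate are fixed points whose
per-frame coordinates are jittered only by isotropic localization noise (the
sub-10-nm regime observed for condensate-resident transcription factors);
free molecules follow 2D Brownian motion with per-axis step variance
2·D·Δt plus the same noise.  Photophysics enters only as finite track length
— there are no blinking gaps, matching a linker that forbids gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ContactRecord,
    GenerationError,
    GenomicInterval,
    ImageFrame,
    Localization,
)

__all__ = [
    "SimTruth",
    "gen_smt_localizations",
    "gen_condensate_image",
    "gen_two_color_hubs",
    "gen_frap_trace",
    "gen_genome_fixture",
]


@dataclass
class SimTruth:
    """Ground truth written by the generators; fields are filled per dataset."""

    rng_seed: int
    # single-molecule tracking
    track_id: np.ndarray | None = None          # per localization
    label: np.ndarray | None = None             # per localization: "bound"/"free"
    track_label: dict[int, str] | None = None   # per planted track
    d_free_um2_s: float | None = None
    sigma_loc_nm: float | None = None
    condensate_centers_nm: np.ndarray | None = None
    condensate_radius_nm: float | None = None
    # condensate images
    blob_masks: list[np.ndarray] | None = None
    blob_areas_um2: list[float] | None = None
    # two-color hubs
    hub_centers_nm: np.ndarray | None = None
    hub_classes: list[str] | None = None
    # FRAP
    plateau: float | None = None
    tau_s: float | None = None
    bleach_depth: float | None = None
    # genomics
    motif_intervals: list[GenomicInterval] | None = None
    motif_sequences: list[str] | None = None
    peaks_with_motif: list[bool] | None = None
    contact_strong: list[bool] | None = None
    contact_in_regions: list[bool] | None = None


# ---------------------------------------------------------------------------
# single-molecule tracking


def _grid_positions(n: int, spacing_nm: float, rng: np.random.Generator) -> np.ndarray:
    """n well-separated anchor positions (nm) on a jittered square grid."""
    side = math.ceil(math.sqrt(n))
    ix, iy = np.divmod(np.arange(n), side)
    pos = np.column_stack([ix, iy]).astype(float) * spacing_nm
    pos += rng.uniform(-0.05, 0.05, size=pos.shape) * spacing_nm
    return pos


def gen_smt_localizations(
    n_bound: int,
    n_free: int,
    d_free: float,
    sigma_loc: float,
    n_frames: int,
    frame_interval: float = 20.0,
    condensate_centers: np.ndarray | None = None,
    min_particle_spacing: float = 2000.0,
    seed: int = 0,
) -> tuple[list[Localization], SimTruth]:
    """Simulate a mixed stream of condensate-bound and freely diffusing molecules.

    Parameters
    ----------
    d_free : diffusion coefficient of the free population, µm²/s.
    sigma_loc : per-axis localization noise, nm.
    frame_interval : ms between frames.
    condensate_centers : optional (n_bound, 2) nm positions; auto-placed on a
        well-separated grid when omitted.
    min_particle_spacing : minimum distance (nm) any two distinct molecules may
        approach; the generator verifies it over all consecutive-frame pairs
        and raises :class:`GenerationError` if violated, so that linking on
        the output is unambiguous.

    Returns the localizations (frame-major order) and the ground truth with
    per-localization track ids and bound/free labels.
    """
    if min(n_bound, n_free, n_frames) < 0 or n_frames == 0:
        raise ValueError("counts must be >= 0 and n_frames >= 1")
    if sigma_loc < 0 or d_free < 0 or frame_interval <= 0:
        raise ValueError("noise, diffusion and frame interval must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_bound + n_free
    if n == 0:
        return [], SimTruth(rng_seed=seed, track_id=np.array([], dtype=int),
                            label=np.array([], dtype=object), track_label={})

    dt_s = frame_interval / 1000.0
    step_sd_nm = math.sqrt(2.0 * d_free * dt_s) * 1000.0  # per axis
    # Anchor spacing: worst-case approach = spacing − 2 × (free excursion + noise).
    excursion = 6.0 * (step_sd_nm * math.sqrt(n_frames) + sigma_loc)
    # 1.25 head-room absorbs the ±5% grid jitter of the anchor positions
    spacing = (min_particle_spacing + 2.0 * excursion) * 1.25
    anchors = _grid_positions(n, spacing, rng)
    rng.shuffle(anchors, axis=0)

    if condensate_centers is not None:
        condensate_centers = np.asarray(condensate_centers, dtype=float)
        if len(condensate_centers) < n_bound:
            raise GenerationError(
                f"{n_bound} bound molecules but only {len(condensate_centers)} "
                "condensate centers"
            )
        anchors[:n_bound] = condensate_centers[:n_bound]

    # Trajectories as (n, n_frames, 2) true positions.
    true_pos = np.repeat(anchors[:, None, :], n_frames, axis=1)
    if n_free:
        steps = rng.normal(0.0, step_sd_nm, size=(n_free, n_frames - 1, 2))
        true_pos[n_bound:, 1:, :] += np.cumsum(steps, axis=1)
    observed = true_pos + rng.normal(0.0, sigma_loc, size=true_pos.shape)

    # Enforce the spacing contract on consecutive-frame cross-particle distances.
    if n > 1:
        from scipy.spatial import cKDTree

        for f in range(n_frames - 1):
            pts = np.vstack([observed[:, f, :], observed[:, f + 1, :]])
            owner = np.concatenate([np.arange(n), np.arange(n)])
            tree = cKDTree(pts)
            for i, j in tree.query_pairs(min_particle_spacing):
                if owner[i] != owner[j]:
                    raise GenerationError(
                        f"particles {owner[i]} and {owner[j]} approach within "
                        f"{min_particle_spacing} nm near frame {f}; increase spacing"
                    )

    locs: list[Localization] = []
    track_id: list[int] = []
    label: list[str] = []
    labels = ["bound"] * n_bound + ["free"] * n_free
    for f in range(n_frames):
        for i in range(n):
            locs.append(Localization(frame=f, x=float(observed[i, f, 0]),
                                     y=float(observed[i, f, 1])))
            track_id.append(i)
            label.append(labels[i])

    truth = SimTruth(
        rng_seed=seed,
        track_id=np.array(track_id, dtype=int),
        label=np.array(label, dtype=object),
        track_label={i: labels[i] for i in range(n)},
        d_free_um2_s=d_free,
        sigma_loc_nm=sigma_loc,
        condensate_centers_nm=anchors[:n_bound].copy(),
        condensate_radius_nm=50.0,
    )
    return locs, truth


def trajectories_from_truth(locs: list[Localization], truth: SimTruth):
    """Reassemble the generator's ground-truth tracks as Trajectory objects.

    Bypasses linking entirely: each planted track id becomes one trajectory,
    regardless of how far the molecule moved between frames.
    """
    from .io import Trajectory

    by_track: dict[int, list[Localization]] = {}
    for p, tid in zip(locs, truth.track_id):
        by_track.setdefault(int(tid), []).append(p)
    out = []
    for tid in sorted(by_track):
        pts = sorted(by_track[tid], key=lambda p: p.frame)
        out.append(Trajectory(tid, pts))
    return out


# ---------------------------------------------------------------------------
# condensate images


def _blob_mask(area_px: float, shape: tuple[int, int], center: tuple[float, float],
               rng: np.random.Generator) -> np.ndarray:
    """Filled irregular blob: an ellipse-like polygon with perturbed radius."""
    from skimage.draw import polygon

    r0 = math.sqrt(area_px / math.pi)
    theta = np.linspace(0.0, 2.0 * math.pi, 72, endpoint=False)
    ecc = rng.uniform(0.8, 1.25)
    wobble = 1.0 + 0.12 * np.cos(rng.integers(2, 5) * theta + rng.uniform(0, 2 * math.pi))
    radius = r0 * wobble * np.sqrt(ecc * np.cos(theta) ** 2 + np.sin(theta) ** 2 / ecc)
    rr, cc = polygon(center[0] + radius * np.sin(theta),
                     center[1] + radius * np.cos(theta), shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def gen_condensate_image(
    blob_areas: list[float],
    pixel_size: float = 0.1,
    noise_sd: float = 2.0,
    seed: int = 0,
    background: float = 20.0,
    amplitude: float = 200.0,
    max_tries: int = 200,
) -> tuple[ImageFrame, SimTruth]:
    """Render an image of irregular bright condensates with known pixel areas.

    ``blob_areas`` are requested areas in µm²; the truth records the *actual*
    rasterized mask of each blob and its area (pixel count × pixel_size²).
    Blobs are placed without overlap (with a 4-px margin); background is
    Gaussian noise around a constant offset.
    """
    rng = np.random.default_rng(seed)
    areas_px = [a / pixel_size**2 for a in blob_areas]
    if any(a <= 0 for a in areas_px):
        raise ValueError("blob areas must be positive")
    radii = [math.sqrt(a / math.pi) * 1.4 + 4 for a in areas_px]
    side = max(128, int(4 * math.sqrt(sum(areas_px) + 1) + 8 * max(radii, default=0)))
    shape = (side, side)

    masks: list[np.ndarray] = []
    centers: list[tuple[float, float]] = []
    for a_px, r in zip(areas_px, radii):
        for _ in range(max_tries):
            c = tuple(rng.uniform(r, side - r, size=2))
            if all(math.hypot(c[0] - c0[0], c[1] - c0[1]) > r + r0
                   for c0, r0 in zip(centers, radii)):
                break
        else:
            raise GenerationError(
                f"could not place blob of {a_px:.0f} px without overlap"
            )
        masks.append(_blob_mask(a_px, shape, c, rng))
        centers.append(c)

    img = background + rng.normal(0.0, noise_sd, size=shape)
    for mask in masks:
        img[mask] += amplitude
    truth = SimTruth(
        rng_seed=seed,
        blob_masks=masks,
        blob_areas_um2=[float(m.sum()) * pixel_size**2 for m in masks],
    )
    return ImageFrame(img, pixel_size), truth


# ---------------------------------------------------------------------------
# two-color pulse-chase hubs


def gen_two_color_hubs(
    n_both: int,
    n_old_only: int,
    n_new_only: int,
    hub_radius: float = 300.0,
    field: float = 20.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    amplitude: float = 500.0,
    noise_sd: float = 2.0,
) -> tuple[ImageFrame, ImageFrame, SimTruth]:
    """Render a two-channel hub field with planted age classes.

    Each hub is a bright Gaussian spot of sd ``hub_radius`` (nm) present in the
    old channel, the new channel, or both, according to its planted class.
    Hubs are placed non-overlapping (≥ 6 spot radii apart).
    """
    rng = np.random.default_rng(seed)
    n = n_both + n_old_only + n_new_only
    classes = (["both"] * n_both + ["old_only"] * n_old_only
               + ["new_only"] * n_new_only)
    side = int(field / pixel_size)
    shape = (side, side)
    r_px = hub_radius / 1000.0 / pixel_size
    centers: list[tuple[float, float]] = []
    margin = 4 * r_px + 2
    for _ in range(n):
        for _ in range(500):
            c = tuple(rng.uniform(margin, side - margin, size=2))
            if all(math.hypot(c[0] - c0[0], c[1] - c0[1]) > 6 * r_px for c0 in centers):
                break
        else:
            raise GenerationError("could not place hubs without overlap; enlarge field")
        centers.append(c)
    order = rng.permutation(n)
    centers = [centers[i] for i in order]  # decouple class from placement order

    yy, xx = np.mgrid[0:side, 0:side]
    old_img = rng.normal(0.0, noise_sd, size=shape) + 10.0
    new_img = rng.normal(0.0, noise_sd, size=shape) + 10.0
    for c, cls in zip(centers, classes):
        spot = amplitude * np.exp(-((yy - c[0]) ** 2 + (xx - c[1]) ** 2) / (2 * r_px**2))
        if cls in ("both", "old_only"):
            old_img += spot
        if cls in ("both", "new_only"):
            new_img += spot
    centers_nm = (np.array(centers, dtype=float).reshape(-1, 2)[:, ::-1]
                  * pixel_size * 1000.0)  # (x, y) nm
    truth = SimTruth(rng_seed=seed, hub_centers_nm=centers_nm, hub_classes=classes)
    return (ImageFrame(old_img, pixel_size, channel=0),
            ImageFrame(new_img, pixel_size, channel=1), truth)


# ---------------------------------------------------------------------------
# FRAP traces


def gen_frap_trace(
    plateau: float,
    tau: float,
    bleach_depth: float = 0.1,
    n_pre: int = 5,
    n_post: int = 120,
    dt: float = 5.0,
    noise_sd: float = 0.0,
    baseline: float = 1000.0,
    seed: int = 0,
) -> tuple["FrapTrace", SimTruth]:
    """Simulate a photobleaching recovery trace.

    Pre-bleach intensity is constant at ``baseline``; after the bleach the
    normalized signal follows ``bleach_depth + (plateau − bleach_depth)·
    (1 − exp(−t/τ))`` with multiplicative scale ``baseline`` and additive
    Gaussian noise of sd ``noise_sd`` (as a fraction of baseline).
    """
    if not 0.0 <= plateau <= 1.0:
        raise ValueError("plateau must be in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    t_pre = np.arange(-n_pre, 0) * dt
    t_post = np.arange(0, n_post) * dt
    pre = np.full(n_pre, 1.0)
    post = bleach_depth + (plateau - bleach_depth) * (1.0 - np.exp(-t_post / tau))
    signal = np.concatenate([pre, post]) * baseline
    from .imaging import FrapTrace

    if noise_sd:
        signal = signal + rng.normal(0.0, noise_sd * baseline, size=signal.shape)
    trace = FrapTrace(np.concatenate([t_pre, t_post]), signal, bleach_index=n_pre)
    truth = SimTruth(rng_seed=seed, plateau=plateau, tau_s=tau,
                     bleach_depth=bleach_depth)
    return trace, truth


# ---------------------------------------------------------------------------
# genome fixture


def gen_genome_fixture(
    seq_len: int = 200_000,
    n_motifs: int = 10,
    n_peaks: int = 20,
    n_contacts: int = 200,
    strong_fraction: float = 0.25,
    resolution: int = 5000,
    pattern: "object | None" = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[GenomicInterval], list[ContactRecord], SimTruth]:
    """Generate a two-chromosome genome with planted composite motifs,
    peaks, and a trans-contact list with planted strong pairs.

    Returns ``(sequences, peaks, contacts, truth)`` where ``sequences`` maps
    chromosome name to sequence.  Planted motifs instantiate the composite
    pattern (one concrete allowed base per class) at non-overlapping
    positions on random strands; roughly half the peaks are centered on
    motifs (containing ≥ 90 % of the motif), the rest are background.
    Contacts join bins of the two chromosomes; ``round(strong_fraction ·
    n_contacts)`` of them are drawn above the strong cutoff of 2, the rest
    below.  The truth records motif intervals, which peaks contain a
    ≥ 90 %-covered motif, and which contacts are strong.
    """
    from .genomics import COMPOSITE_PATTERN_TEXT, parse_pattern

    if pattern is None:
        pattern = parse_pattern(COMPOSITE_PATTERN_TEXT)
    rng = np.random.default_rng(seed)
    plen = len(pattern.classes)
    half = seq_len // 2
    chrom_names = ("chr1", "chr2")
    if n_motifs * plen * 4 > half:
        raise GenerationError(f"sequence of {seq_len} bp too small for {n_motifs} motifs")

    bases = np.array(list("ACGT"))
    seqs = {name: rng.choice(bases, size=half) for name in chrom_names}

    # Plant motifs on chr1 at non-overlapping positions.
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    motif_ivs: list[GenomicInterval] = []
    motif_seqs: list[str] = []
    taken: list[tuple[int, int]] = []
    for _ in range(n_motifs):
        for _ in range(1000):
            start = int(rng.integers(0, half - plen))
            if all(start + plen + 10 <= s or start >= e + 10 for s, e in taken):
                break
        else:
            raise GenerationError("could not place motifs without overlap")
        taken.append((start, start + plen))
        inst = "".join(str(rng.choice(sorted(cls))) for cls in pattern.classes)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = inst if strand == "+" else "".join(comp[b] for b in reversed(inst))
        seqs["chr1"][start:start + plen] = list(planted)
        motif_ivs.append(GenomicInterval("chr1", start, start + plen, strand))
        motif_seqs.append(inst)

    # Peaks: half centered on planted motifs, half background.
    peaks: list[GenomicInterval] = []
    peaks_with_motif: list[bool] = []
    n_on_motif = min(n_peaks // 2, n_motifs)
    for iv in motif_ivs[:n_on_motif]:
        pad = int(rng.integers(50, 200))
        start = max(0, iv.start - pad)
        peaks.append(GenomicInterval("chr1", start, min(half, iv.end + pad)))
        peaks_with_motif.append(True)
    for _ in range(n_peaks - n_on_motif):
        width = int(rng.integers(200, 600))
        for _ in range(1000):
            start = int(rng.integers(0, half - width))
            cand = GenomicInterval("chr1", start, start + width)
            # Background peaks must not graze a planted motif.
            if all(cand.overlap(iv) == 0 for iv in motif_ivs):
                break
        else:
            raise GenerationError("could not place background peaks")
        peaks.append(cand)
        peaks_with_motif.append(False)

    # Trans contacts between chr1 and chr2 bins; strong values above the
    # cutoff of 2, weak below.
    n_strong = round(strong_fraction * n_contacts)
    n_bins = half // resolution
    if n_contacts > n_bins * n_bins:
        raise GenerationError(
            f"{n_contacts} distinct bin pairs requested but only {n_bins * n_bins} "
            f"exist at {resolution} bp over {half} bp chromosomes"
        )
    pair_ids = rng.choice(n_bins * n_bins, size=n_contacts, replace=False)
    contacts: list[ContactRecord] = []
    contact_strong: list[bool] = []
    for k, pid in enumerate(pair_ids):
        ba = int(pid // n_bins) * resolution
        bb = int(pid % n_bins) * resolution
        strong = k < n_strong
        value = float(rng.uniform(2.2, 8.0)) if strong else float(rng.uniform(0.02, 1.8))
        contacts.append(ContactRecord("chr1", ba, "chr2", bb, resolution, value))
        contact_strong.append(strong)
    order = rng.permutation(n_contacts)
    contacts = [contacts[i] for i in order]
    contact_strong = [contact_strong[i] for i in order]

    sequences = {name: "".join(arr) for name, arr in seqs.items()}
    truth = SimTruth(
        rng_seed=seed,
        motif_intervals=motif_ivs,
        motif_sequences=motif_seqs,
        peaks_with_motif=peaks_with_motif,
        contact_strong=contact_strong,
    )
    return sequences, peaks, contacts, truth
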