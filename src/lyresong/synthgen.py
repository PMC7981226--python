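"""Synthetic whistle-song corpora with known dialect structure.

The generator emulates the study design the analysis assumes: six
populations of five to six males in patchy montane habitat, each male
recorded singing up to 30 whistle songs. A whistle song is ~5 s long and
has three components: 1-3 short broadband introductory elements near
2.8 kHz, a variable multi-element body, and a single ascending final
element near 2.3 kHz (optionally replaced by a broadband "buzz").

Dialect structure is injected at the population level as frequency
offsets (Hz) applied per component:

* body and final offsets are drawn jointly across populations with
  Brownian-motion covariance over the geographic distance matrix, so the
  expected squared difference between two population means grows linearly
  with their separation (isolation by distance);
* intro offsets are i.i.d. across populations — distance-independent.

Every generated element carries a ground-truth record, and "true"
acoustic measurements can be derived directly from element parameters so
the statistical pipeline can be exercised without audio synthesis.
Waveform rendering (linear chirps, Hann envelopes, optional pink noise)
is provided for testing the measurement stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import ResistanceRaster, geo_distance_matrices

# Default population layout: six sites spread over ~100 km in SE Queensland /
# NE New South Wales montane forest (approximate study region), (lon, lat).
DEFAULT_POP_COORDS = (
    (153.13, -28.37),  # P1 (Border Ranges-like)
    (153.13, -28.23),  # P2 (Lamington-like)
    (153.33, -28.52),  # P3 (Mt Jerusalem-like)
    (153.19, -27.92),  # P4 (Tamborine-like)
    (152.57, -28.33),  # P5 (Killarney-like)
    (152.42, -28.05),  # P6 (Goomburra-like)
)

INTRO_PEAK_HZ = 2790.0      # field mean 2.79 kHz
INTRO_DURATION_S = 0.100    # field mean 0.100 s
FINAL_START_HZ = 2050.0
FINAL_RISE_HZ = 500.0       # ascending final, peak ~2.3 kHz
BODY_BASE_HZ = 2000.0
INTRO_BODY_PAUSE_S = 1.28   # field mean; sd 0.85, truncated below
INTRO_BODY_PAUSE_SD = 0.85


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for a synthetic corpus.

    Divergence rates are in Hz of population-mean offset: after a
    separation of d km, the sd of the difference between two population
    means is ``rate * sqrt(d)`` per dialect dimension (Brownian drift).
    ``intro_divergence`` is the i.i.d. per-population offset sd in Hz.
    """

    n_populations: int = 6
    individuals_per_pop: int = 5
    songs_per_individual: int = 30
    pop_coordinates: tuple = DEFAULT_POP_COORDS
    body_divergence_rate: float = 80.0    # Hz per sqrt(km)
    intro_divergence: float = 300.0       # Hz, i.i.d. per population
    final_divergence_rate: float = 20.0   # Hz per sqrt(km), small
    within_individual_sd: float = 30.0    # Hz, song-to-song
    within_population_sd: float = 40.0    # Hz, individual-to-individual
    body_variant_sd: float = 60.0         # Hz, variant offsets within a population
    n_body_variants_per_pop: int = 2
    n_dialect_dims: int = 4               # roles: shift, tilt, duration, sweep (, spread)
    drift_stochasticity: float = 0.1      # fraction of divergence variance that is random
    buzz_probability: float = 0.237       # field rate in the one buzzing population
    buzz_populations: tuple = (5,)        # population indices that may buzz
    noise_snr_db: float | None = 20.0
    sample_rate: int = 32000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_populations", "individuals_per_pop", "songs_per_individual",
                     "n_body_variants_per_pop", "n_dialect_dims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("body_divergence_rate", "intro_divergence", "final_divergence_rate",
                     "within_individual_sd", "within_population_sd", "body_variant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate < 8000:
            raise ValueError("sample_rate must be >= 8000 Hz")
        if not 0.0 <= self.drift_stochasticity <= 1.0:
            raise ValueError("drift_stochasticity must be in [0, 1]")
        if len(self.pop_coordinates) < self.n_populations:
            raise ValueError("need one coordinate per population")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class ElementSpec:
    """Idealised song element: a linear chirp with some spectral width."""

    onset_s: float
    duration_s: float
    f_start_Hz: float
    f_end_Hz: float
    bandwidth_Hz: float
    amplitude: float = 1.0
    component: str = "body"   # intro | body | final | buzz_final

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.f_start_Hz <= 0 or self.f_end_Hz <= 0:
            raise ValueError("frequencies must be positive")


@dataclass
class Dialects:
    """Per-population component mean offsets (Hz)."""

    body: np.ndarray      # (n_pop, n_dims)
    intro: np.ndarray     # (n_pop, n_dims)
    final: np.ndarray     # (n_pop, 1)
    body_variants: np.ndarray  # (n_pop, n_variants, n_dims)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def generate_landscape(n_rows, n_cols, cellsize, corridor_spec=None, seed=0, *,
                       origin=(0.0, 0.0), crs="projected_m",
                       background=0.8, corridor_resistance=0.05,
                       noise_sd=0.02) -> ResistanceRaster:
    """Resistance raster with optional low-resistance corridors.

    ``corridor_spec`` is None (uniform background) or a list of
    ``((x1, y1), (x2, y2))`` endpoint pairs; cells on the straight segment
    between each pair (1-cell wide) get ``corridor_resistance``, strictly
    lower than the (optionally noisy) background.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("raster must be at least 2x2")
    rng = np.random.default_rng(seed)
    vals = np.full((n_rows, n_cols), background, dtype=float)
    if noise_sd > 0 and corridor_spec is not None:
        vals += rng.normal(0.0, noise_sd, vals.shape)
    hi = 1.0
    lo = corridor_resistance
    vals = np.clip(vals, lo + 0.05, hi)
    raster = ResistanceRaster(vals, origin, cellsize, crs=crs)
    if corridor_spec:
        for (p, q) in corridor_spec:
            r1, c1 = raster.cell_of(*p)
            r2, c2 = raster.cell_of(*q)
            n = max(abs(r2 - r1), abs(c2 - c1), 1)
            for t in np.linspace(0.0, 1.0, 2 * n + 1):
                r = int(round(r1 + t * (r2 - r1)))
                c = int(round(c1 + t * (c2 - c1)))
                raster.values[r, c] = lo
    return raster


def default_landscape(config: SynthConfig, seed=None) -> ResistanceRaster:
    """Geographic-CRS landscape covering the default populations.

    Corridors chain the populations along a near-minimal spanning tree of
    their straight-line distances, so least-cost routes between distant
    sites detour through intermediate habitat (as ridgelines do).
    """
    coords = list(config.pop_coordinates[: config.n_populations])
    lons = [c[0] for c in coords]
    lats = [c[1] for c in coords]
    pad = 0.15
    cell = 0.02
    x0, y0 = min(lons) - pad, min(lats) - pad
    n_cols = int(math.ceil((max(lons) + pad - x0) / cell)) + 1
    n_rows = int(math.ceil((max(lats) + pad - y0) / cell)) + 1
    # minimal spanning tree over straight-line distances -> corridor pairs
    _, straight, _ = geo_distance_matrices({str(i): c for i, c in enumerate(coords)})
    n = len(coords)
    in_tree = {0}
    corridors = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j in in_tree:
                    continue
                if best is None or straight[i, j] < best[0]:
                    best = (straight[i, j], i, j)
        _, i, j = best
        in_tree.add(j)
        corridors.append((coords[i], coords[j]))
    return generate_landscape(
        n_rows, n_cols, cell, corridors,
        seed=config.seed if seed is None else seed,
        origin=(x0, y0), crs="geographic",
    )


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

def _brownian_eig(dist_km: np.ndarray, rate: float, ref: int = 0):
    """Eigendecomposition of the Brownian covariance over the distance matrix.

    The covariance C_ij = rate^2/2 (d_ref,i + d_ref,j - d_ij) satisfies
    E(x_i - x_j)^2 = rate^2 d_ij; small negative eigenvalues (metric not
    exactly of negative type) are clipped. Returns eigenvalues (descending)
    and eigenvectors.
    """
    d0 = dist_km[ref]
    cov = 0.5 * rate ** 2 * (d0[:, None] + d0[None, :] - dist_km)
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0.0, None), v[:, order]


def _distance_coupled_means(dist_km, rate, m, stochasticity, rng):
    """Population mean offsets with E||mu_i - mu_j||^2 = rate^2 d_ij.

    A fraction ``1 - stochasticity`` of the divergence variance comes from
    a deterministic isometric embedding of the sqrt-distance metric (the
    expectation part of Brownian drift: the scaled eigenvectors of the
    Brownian covariance); the remaining fraction is a random Brownian
    field. When ``m`` is at least the embedding rank the law holds exactly
    per pair; a lower ``m`` truncates the embedding (total variance is
    rescaled to compensate).
    """
    n = dist_km.shape[0]
    w, v = _brownian_eig(dist_km, rate)
    keep = min(m, int((w > 1e-12 * max(w.max(), 1.0)).sum()))
    E = np.zeros((n, m))
    if keep:
        scale = math.sqrt(w.sum() / w[:keep].sum()) if w[:keep].sum() > 0 else 1.0
        E[:, :keep] = v[:, :keep] * np.sqrt(w[:keep]) * scale
    # each of the m dims carries 1/m of the stochastic variance so the
    # total squared difference matches rate^2 d
    B = (v * np.sqrt(w)) @ rng.standard_normal((n, m)) / math.sqrt(m)
    s = stochasticity
    return math.sqrt(1.0 - s) * E + math.sqrt(s) * B


def generate_dialects(config: SynthConfig, geo_dist_m: np.ndarray,
                      rng=None) -> Dialects:
    """Population component mean offsets with the configured distance coupling.

    ``geo_dist_m`` is the symmetric pairwise geographic distance matrix in
    metres (zero diagonal). Body and final offsets follow the
    distance-coupled drift model (expected squared mean difference =
    rate^2 x distance in km, deterministic cline plus Brownian residual
    mixed by ``drift_stochasticity``); intro offsets are i.i.d.
    N(0, intro_divergence^2) across populations — distance-independent.
    """
    d = np.asarray(geo_dist_m, dtype=float)
    if d.shape != (config.n_populations,) * 2:
        raise ValueError("distance matrix shape does not match n_populations")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d_km = d / 1000.0
    m = config.n_dialect_dims
    s = config.drift_stochasticity

    body = _distance_coupled_means(d_km, config.body_divergence_rate, m, s, rng)
    final = _distance_coupled_means(d_km, config.final_divergence_rate, 2, s, rng)
    intro = rng.normal(0.0, config.intro_divergence, (config.n_populations, m))
    variants = rng.normal(0.0, config.body_variant_sd,
                          (config.n_populations, config.n_body_variants_per_pop, m))
    return Dialects(body=body, intro=intro, final=final, body_variants=variants)


# ---------------------------------------------------------------------------
# songs
# ---------------------------------------------------------------------------

def assemble_song(population: int, individual: int, config: SynthConfig,
                  rng, dialects: Dialects, indiv_offset=0.0,
                  variant: int | None = None) -> list[ElementSpec]:
    """Build one whistle song as an ordered list of element specs.

    Always yields a valid song: 1-3 intro elements, an intro-body pause
    around 1.28 s, 5-25 body elements from the individual's variant, and
    exactly one final element (ascending, or a broadband buzz when the
    population buzzes with the configured probability).

    The dialect offset dimensions act as coherent acoustic roles rather
    than per-element perturbations — a population differs from another in
    how the whole song sits and moves in frequency:

    0. uniform frequency shift of the component (Hz);
    1. frequency tilt across the body (early vs late elements);
    2. duration scaling (an offset of x Hz scales durations by 1 + x/2000);
    3. element sweep-width scaling;
    4. alternating-element frequency spread (even vs odd elements).

    The first four are signed quantities the song-level summaries measure
    almost linearly (level, slope, duration, bandwidth); the spread role —
    whose sign the summaries fold away — is used only when
    ``n_dialect_dims`` exceeds 4.
    """
    m = config.n_dialect_dims
    if variant is None:
        variant = int(rng.integers(config.n_body_variants_per_pop))
    jitter = lambda: rng.normal(0.0, config.within_individual_sd)
    scale = lambda off: float(np.clip(1.0 + off / 2000.0, 0.5, 2.0))
    # individuals vary in every dialect role, not just baseline pitch
    io = np.broadcast_to(np.asarray(indiv_offset, dtype=float).ravel(), (m,))

    elements: list[ElementSpec] = []
    t = 0.0
    # --- intro: 1-3 short broadband elements near 2.8 kHz
    idm = dialects.intro[population]
    n_intro = int(rng.integers(1, 4))
    for i in range(n_intro):
        f = INTRO_PEAK_HZ + idm[0] + io[0] + jitter()
        f = max(f, 300.0)
        dur = max(0.03, rng.normal(INTRO_DURATION_S, 0.02)
                  * (scale(idm[1]) if m > 1 else 1.0))
        bw = max(200.0, rng.normal(600.0, 80.0) * (scale(idm[2]) if m > 2 else 1.0))
        elements.append(ElementSpec(t, dur, f, f, bandwidth_Hz=bw,
                                    component="intro"))
        t += dur + max(0.05, rng.normal(0.15, 0.04))
    # --- intro-body pause, truncated so it stays a recognisable pause
    t = elements[-1].onset_s + elements[-1].duration_s
    t += float(np.clip(rng.normal(INTRO_BODY_PAUSE_S, INTRO_BODY_PAUSE_SD), 0.3, 3.0))
    # --- body: 5-25 elements of the individual's variant (typically ~16,
    # keeping total song duration near 5 s)
    n_body = int(np.clip(round(rng.normal(16.0, 3.0)), 5, 25))
    bd = (dialects.body[population] + dialects.body_variants[population, variant]
          + io)
    shift = bd[0]
    tilt = bd[1] if m > 1 else 0.0
    dur_scale = scale(bd[2]) if m > 2 else 1.0
    sweep_scale = scale(bd[3]) if m > 3 else 1.0
    spread = bd[4] if m > 4 else 0.0
    for s in range(n_body):
        base = BODY_BASE_HZ + 300.0 * math.sin(2 * math.pi * s / 7.0)
        frac = s / max(n_body - 1, 1) - 0.5
        f = (base + shift + tilt * frac + (spread / 2 if s % 2 else -spread / 2)
             + jitter())
        f = max(f, 300.0)
        sweep = (max(50.0, rng.normal(200.0, 40.0) * sweep_scale)
                 * (1.0 if s % 2 == 0 else -1.0))
        dur = max(0.05, rng.normal(0.15, 0.04) * dur_scale)
        elements.append(ElementSpec(t, dur, f - sweep / 2, f + sweep / 2,
                                    bandwidth_Hz=max(40.0, rng.normal(100.0, 25.0)),
                                    component="body"))
        t += dur + max(0.03, rng.normal(0.12, 0.03))
    # --- final: ascending, or broadband buzz
    buzz = (population in config.buzz_populations
            and rng.random() < config.buzz_probability)
    t += 0.1
    if buzz:
        f = 2300.0 + io[0] + jitter()
        elements.append(ElementSpec(t, max(0.1, rng.normal(0.35, 0.05)), f, f,
                                    bandwidth_Hz=max(2000.0, rng.normal(2500.0, 200.0)),
                                    component="buzz_final"))
    else:
        f0 = FINAL_START_HZ + dialects.final[population, 0] + io[0] + jitter()
        f0 = max(f0, 300.0)
        rise = max(200.0, rng.normal(FINAL_RISE_HZ, 50.0)
                   * scale(dialects.final[population, 1 % dialects.final.shape[1]]))
        elements.append(ElementSpec(t, max(0.1, rng.normal(0.4, 0.05)),
                                    f0, f0 + rise,
                                    bandwidth_Hz=max(40.0, rng.normal(100.0, 25.0)),
                                    component="final"))
    return elements


def true_measures(el: ElementSpec) -> dict:
    """Noise-free acoustic measurements implied by an element spec.

    These mirror what the measurement stack recovers from a rendered
    chirp: 90% of the energy spans 90% of the duration and of the swept
    band, the peak/centre frequency sits mid-sweep, and the contour runs
    from f_start to f_end.
    """
    lo = min(el.f_start_Hz, el.f_end_Hz) - el.bandwidth_Hz / 2
    hi = max(el.f_start_Hz, el.f_end_Hz) + el.bandwidth_Hz / 2
    return {
        "begin_s": el.onset_s,
        "end_s": el.onset_s + el.duration_s,
        "duration90_s": 0.9 * el.duration_s,
        "peak_freq_Hz": 0.5 * (el.f_start_Hz + el.f_end_Hz),
        "center_freq_Hz": 0.5 * (el.f_start_Hz + el.f_end_Hz),
        "bandwidth90_Hz": 0.9 * (abs(el.f_end_Hz - el.f_start_Hz) + el.bandwidth_Hz),
        "freq5_Hz": lo + 0.05 * (hi - lo),
        "freq95_Hz": lo + 0.95 * (hi - lo),
        "first_freq_Hz": el.f_start_Hz,
        "last_freq_Hz": el.f_end_Hz,
        "slope_Hz": el.f_end_Hz - el.f_start_Hz,
    }


def generate_corpus(config: SynthConfig, dialects: Dialects | None = None,
                    geo_dist_m: np.ndarray | None = None):
    """Full synthetic corpus: element table, song metadata, dialects.

    Returns ``(elements, songs, dialects)``. ``elements`` is a DataFrame of
    ground-truth element measurements (one row per element, with song_id,
    population, individual, element_index and the true component label);
    ``songs`` holds per-song metadata including the element specs needed to
    render audio.
    """
    rng = np.random.default_rng(config.seed)
    if dialects is None:
        if geo_dist_m is None:
            pops = {f"P{i+1}": c for i, c in
                    enumerate(config.pop_coordinates[: config.n_populations])}
            _, geo_dist_m, _ = geo_distance_matrices(pops)
        dialects = generate_dialects(config, geo_dist_m, rng=rng)

    rows, songs = [], []
    song_id = 0
    for p in range(config.n_populations):
        for i in range(config.individuals_per_pop):
            indiv = f"P{p+1}_M{i+1}"
            indiv_offset = rng.normal(0.0, config.within_population_sd,
                                      config.n_dialect_dims)
            for s in range(config.songs_per_individual):
                variant = int(rng.integers(config.n_body_variants_per_pop))
                els = assemble_song(p, i, config, rng, dialects,
                                    indiv_offset=indiv_offset, variant=variant)
                sid = f"S{song_id:05d}"
                song_id += 1
                songs.append({"song_id": sid, "population": f"P{p+1}",
                              "individual": indiv, "variant": variant,
                              "elements": els})
                for k, el in enumerate(els):
                    rows.append({"song_id": sid, "population": f"P{p+1}",
                                 "individual": indiv, "element_index": k,
                                 "true_component": el.component,
                                 **true_measures(el)})
    elements = pd.DataFrame(rows)
    songs_df = pd.DataFrame(songs)
    return elements, songs_df, dialects


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng) -> np.ndarray:
    """Approximate 1/f noise by shaping white noise in the rFFT domain."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.arange(len(spec), dtype=float)
    freqs[0] = 1.0
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n)
    return out / (out.std() + 1e-12)


def synthesize_waveform(elements: list[ElementSpec], sample_rate: int,
                        noise_snr_db: float | None = None, rng=None,
                        padding_s: float = 0.25) -> np.ndarray:
    """Render a song to audio: Hann-enveloped linear chirps plus pink noise.

    ``noise_snr_db`` of None (or inf) means noise-free; otherwise pink
    noise is added at the stated SNR measured over the song's active
    region. Raises if any element frequency exceeds Nyquist.
    """
    for el in elements:
        if max(el.f_start_Hz, el.f_end_Hz) + el.bandwidth_Hz / 2 >= sample_rate / 2:
            raise ValueError("element frequency above Nyquist")
    total = padding_s
    if elements:
        total = max(el.onset_s + el.duration_s for el in elements) + padding_s
    n = int(round(total * sample_rate))
    wave = np.zeros(n)
    rng = np.random.default_rng() if rng is None else rng
    for el in elements:
        ns = int(round(el.duration_s * sample_rate))
        if ns < 2:
            continue
        t = np.arange(ns) / sample_rate
        # linear chirp: phase integral of f(t) = f_start + (f_end-f_start) t/T
        sweep = (el.f_end_Hz - el.f_start_Hz) / el.duration_s
        phase = 2 * np.pi * (el.f_start_Hz * t + 0.5 * sweep * t ** 2)
        sig = np.sin(phase)
        if el.bandwidth_Hz > 400.0:
            # widen the band with a second detuned chirp pair
            for df in (-el.bandwidth_Hz / 2, el.bandwidth_Hz / 2):
                phase_d = 2 * np.pi * ((el.f_start_Hz + df) * t + 0.5 * sweep * t ** 2)
                sig = sig + 0.8 * np.sin(phase_d + rng.uniform(0, 2 * np.pi))
        env = np.hanning(ns)
        i0 = int(round(el.onset_s * sample_rate))
        seg = el.amplitude * env * sig
        wave[i0:i0 + ns] += seg[: max(0, n - i0)]
    if noise_snr_db is not None and np.isfinite(noise_snr_db) and elements:
        active = wave != 0
        sig_pow = float(np.mean(wave[active] ** 2)) if active.any() else 0.0
        if sig_pow > 0:
            noise = _pink_noise(n, rng)
            noise_pow = sig_pow / (10 ** (noise_snr_db / 10))
            wave = wave + noise * math.sqrt(noise_pow)
    return wave


def ground_truth_selections(elements: list[ElementSpec]) -> pd.DataFrame:
    """Element specs as a selection table (one box per element)."""
    rows = []
    for k, el in enumerate(elements):
        lo = min(el.f_start_Hz, el.f_end_Hz) - el.bandwidth_Hz / 2 - 150.0
        hi = max(el.f_start_Hz, el.f_end_Hz) + el.bandwidth_Hz / 2 + 150.0
        rows.append({
            "Selection": k + 1, "View": "Spectrogram 1", "Channel": 1,
            "Begin Time (s)": el.onset_s,
            "End Time (s)": el.onset_s + el.duration_s,
            "Low Freq (Hz)": max(50.0, lo), "High Freq (Hz)": hi,
            "component": el.component,
        })
    return pd.DataFrame(rows)
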