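"""Song-component classification and analysis feature tables.

A whistle song is partitioned into three components: up to three short
introductory elements, a variable multi-element body, and a single final
element (ascending whistle, or a broadband "buzz" in some populations).
Labelling is deterministic: intro elements are those preceding the first
long inter-element pause (default threshold 0.6 s, the lower end of the
observed 1.28 +/- 0.85 s intro-body pause), the last element is the
final, and everything in between is body.

Four analysis scopes are derived:

* ``full`` / ``body`` — one row per song with the seven song-level
  variables (duration, 90% song bandwidth, highest/lowest peak frequency,
  CV of peak frequency, CV of 90% duration, song slope);
* ``intro`` / ``final`` — one row per element with five element-level
  variables (90% duration, peak frequency, 90% bandwidth, first and last
  contour frequency).

Skew-correcting transforms (log10 of intro duration; log10 of
4000 - last frequency for finals) are applied before z-scaling; variables
correlated above a threshold are pruned greedily; multivariate outliers
are flagged by Mahalanobis distance against a chi-squared quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

logger = logging.getLogger("lyresong")

INTRO_GAP_THRESHOLD_S = 0.6
MAX_INTRO = 3
BUZZ_BANDWIDTH_HZ = 1500.0   # broadband threshold for buzz detection
BUZZ_SLOPE_HZ = 200.0        # |slope| below this together with wide band -> buzz
FINAL_REFLECTION_HZ = 4000.0  # reflection point for the final-element log transform

ELEMENT_VARS = ["duration90_s", "peak_freq_Hz", "bandwidth90_Hz",
                "first_freq_Hz", "last_freq_Hz"]
SONG_VARS = ["duration_s", "bandwidth90_Hz", "highest_peak_Hz", "lowest_peak_Hz",
             "cv_peak", "cv_duration", "song_slope"]


@dataclass
class LabeledFeatureMatrix:
    """z-scaled analysis matrix with row labels kept alongside."""

    values: pd.DataFrame   # rows x variables, scaled
    labels: pd.DataFrame   # population, individual, song_id (, element_index)
    variables: list

    def __post_init__(self):
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("non-finite entries after scaling")


# ---------------------------------------------------------------------------
# component labelling
# ---------------------------------------------------------------------------

def label_components(song: pd.DataFrame, gap_threshold_s: float = INTRO_GAP_THRESHOLD_S,
                     max_intro: int = MAX_INTRO,
                     buzz_bandwidth_hz: float = BUZZ_BANDWIDTH_HZ,
                     buzz_slope_hz: float = BUZZ_SLOPE_HZ):
    """Label each element of one song; returns (labels, final_absent flag).

    ``song`` is that song's element-measure rows in time order. Elements
    before the first gap exceeding the threshold (searched only among the
    first ``max_intro`` gaps) are intro; the last element is final
    (buzz_final when broadband and flat); the remainder is body. A last
    element that is neither ascending nor a buzz is left as body and the
    song is flagged ``final_absent``.
    """
    n = len(song)
    if n < 2:
        raise ValueError("song must contain at least 2 elements")
    begins = song["begin_s"].to_numpy()
    ends = song["end_s"].to_numpy()
    if not np.all(np.diff(begins) >= 0):
        raise ValueError("elements must be time-ordered")
    gaps = begins[1:] - ends[:-1]

    n_intro = 0
    for i in range(min(max_intro, n - 1)):
        if gaps[i] > gap_threshold_s:
            n_intro = i + 1
            break
    labels = ["intro"] * n_intro + ["body"] * (n - n_intro)

    last = song.iloc[-1]
    final_absent = False
    if (last["bandwidth90_Hz"] > buzz_bandwidth_hz
            and abs(last["slope_Hz"]) < buzz_slope_hz):
        labels[-1] = "buzz_final"
    elif last["slope_Hz"] > 0:
        labels[-1] = "final"
    else:
        final_absent = True
    return labels, final_absent


def label_corpus(elements: pd.DataFrame, **kw) -> pd.DataFrame:
    """Apply :func:`label_components` per song; adds component / final_absent."""
    out = elements.sort_values(["song_id", "begin_s"], kind="stable").copy()
    comp = np.empty(len(out), dtype=object)
    absent = np.zeros(len(out), dtype=bool)
    pos = 0
    for sid, grp in out.groupby("song_id", sort=False):
        labels, fa = label_components(grp, **kw)
        comp[pos:pos + len(grp)] = labels
        absent[pos:pos + len(grp)] = fa
        pos += len(grp)
    out["component"] = comp
    out["final_absent"] = absent
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_songs(songs: pd.DataFrame, per_individual: int = 30, seed=0) -> pd.DataFrame:
    """Uniformly sample up to ``per_individual`` songs per individual.

    Individuals with no more than the quota keep every song; sampling is
    without replacement and deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for indiv, grp in songs.groupby("individual", sort=True):
        if len(grp) <= per_individual:
            keep.append(grp)
        else:
            idx = rng.choice(len(grp), size=per_individual, replace=False)
            keep.append(grp.iloc[np.sort(idx)])
    return pd.concat(keep, ignore_index=True)


# ---------------------------------------------------------------------------
# song-level aggregation (Table-1-style variables)
# ---------------------------------------------------------------------------

def aggregate_song(elements: pd.DataFrame, scope: str = "full_song") -> dict:
    """Seven song-level variables from one song's labelled elements.

    ``scope`` is ``"full_song"`` (all elements) or ``"body_only"``.
    Duration runs from the beginning of the first element to the end of
    the last, inter-element intervals included. The 90% song bandwidth is
    the 95% frequency of the highest-peaked element minus the 5% frequency
    of the lowest-peaked element. CVs are sample sd / mean; the song slope
    is the least-squares slope of element centre frequency against element
    midpoint time. With fewer than two elements the CV and slope fields
    are NaN (flagged missing).
    """
    if scope == "body_only":
        els = elements[elements["component"] == "body"]
    elif scope == "full_song":
        els = elements
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(els) == 0:
        raise ValueError("no elements in scope")

    peaks = els["peak_freq_Hz"].to_numpy()
    durs = els["duration90_s"].to_numpy()
    out = {
        "duration_s": float(els["end_s"].max() - els["begin_s"].min()),
        "bandwidth90_Hz": float(els.loc[els["peak_freq_Hz"].idxmax(), "freq95_Hz"]
                                - els.loc[els["peak_freq_Hz"].idxmin(), "freq5_Hz"]),
        "highest_peak_Hz": float(peaks.max()),
        "lowest_peak_Hz": float(peaks.min()),
    }
    if len(els) >= 2:
        out["cv_peak"] = float(peaks.std(ddof=1) / peaks.mean())
        out["cv_duration"] = float(durs.std(ddof=1) / durs.mean())
        times = 0.5 * (els["begin_s"] + els["end_s"]).to_numpy()
        out["song_slope"] = float(
            spstats.linregress(times, els["center_freq_Hz"].to_numpy()).slope)
    else:
        out["cv_peak"] = out["cv_duration"] = out["song_slope"] = float("nan")
    return out


def song_feature_table(labelled: pd.DataFrame, scope: str = "full_song") -> pd.DataFrame:
    """Per-song Table-1 variables for every song with >= 2 in-scope elements."""
    rows = []
    for sid, grp in labelled.groupby("song_id", sort=True):
        els = grp[grp["component"] == "body"] if scope == "body_only" else grp
        if len(els) < 2:
            logger.info("song %s skipped in scope %s: <2 elements", sid, scope)
            continue
        feats = aggregate_song(grp, scope=scope)
        feats.update(song_id=sid, population=grp["population"].iloc[0],
                     individual=grp["individual"].iloc[0])
        rows.append(feats)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transforms, scaling, pruning, outliers
# ---------------------------------------------------------------------------

def zscale(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Centre and scale the named columns to mean 0 / sd 1."""
    out = table.copy()
    for v in variables:
        col = out[v].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot scale constant or non-finite column {v!r}")
        out[v] = (col - col.mean()) / sd
    return out


def transform_variables(table: pd.DataFrame, analysis: str):
    """Skew transforms + z-scaling for one analysis scope.

    ``analysis`` is one of ``intro``, ``final``, ``body``, ``full``.
    Intro: 90% duration -> log10(duration). Final: last frequency ->
    log10(4000 - last), rows with last >= 4000 Hz excluded (logged).
    Returns ``(LabeledFeatureMatrix, excluded row index)``.
    """
    if analysis in ("intro", "final"):
        variables = list(ELEMENT_VARS)
    elif analysis in ("body", "full"):
        variables = list(SONG_VARS)
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"analysis {analysis!r} requires columns {missing}")

    tab = table.copy()
    excluded = tab.index[:0]
    if analysis == "intro":
        tab["duration90_s"] = np.log10(tab["duration90_s"])
    elif analysis == "final":
        bad = tab["last_freq_Hz"] >= FINAL_REFLECTION_HZ
        if bad.any():
            logger.warning("%d final elements with last frequency >= %g Hz excluded",
                           int(bad.sum()), FINAL_REFLECTION_HZ)
            excluded = tab.index[bad]
            tab = tab[~bad]
        tab["last_freq_Hz"] = np.log10(FINAL_REFLECTION_HZ - tab["last_freq_Hz"])

    tab = zscale(tab, variables)
    label_cols = [c for c in ("population", "individual", "song_id", "element_index")
                  if c in tab.columns]
    mat = LabeledFeatureMatrix(values=tab[variables].reset_index(drop=True),
                               labels=tab[label_cols].reset_index(drop=True),
                               variables=variables)
    return mat, excluded


def prune_correlated(table: pd.DataFrame, threshold: float = 0.7) -> list:
    """Greedy variable pruning until all pairwise |r| < threshold.

    While any pair correlates at or above the threshold, the variable with
    the largest mean absolute correlation to the others is dropped; ties
    break by variable-name order. Returns the retained variable names.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    cols = sorted(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    corr = table[cols].corr().abs()
    if not np.isfinite(corr.to_numpy()).all():
        raise ValueError("non-finite correlations")
    keep = list(cols)
    while len(keep) > 1:
        sub = corr.loc[keep, keep].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        if sub.max() < threshold:
            break
        mean_abs = sub.sum(axis=0) / (len(keep) - 1)
        drop = keep[int(np.argmax(mean_abs))]  # argmax takes first on ties -> name order
        keep.remove(drop)
    return keep


def flag_outliers(scores: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Mahalanobis outlier flags against the chi-squared quantile.

    ``scores`` is (rows, dims); a row is flagged when its squared
    Mahalanobis distance to the global centroid (under the score
    covariance) exceeds the chi2(dims) quantile at 1 - alpha.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < d + 2:
        raise ValueError("need at least dims + 2 rows")
    centred = X - X.mean(axis=0)
    cov = np.cov(centred, rowvar=False).reshape(d, d)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular score covariance") from e
    d2 = np.einsum("ij,jk,ik->i", centred, inv, centred)
    if alpha <= 0:
        return np.zeros(n, dtype=bool)
    return d2 > spstats.chi2.ppf(1 - alpha, df=d)
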