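"""Windowed copy-number scoring against a normal reference and tumor content.

Spots are QC-filtered, then each spot's expression is summarized over
chromosomally contiguous 100-gene windows as a ratio to the reference mean:

    score(spot, window) = exp( mean_window[ log1p(CPM_spot) - log1p(CPM_ref_mean) ] )

The matrix is rescaled per window so reference spots span 0.98-1.02 around a
mean of 1.00. Windows whose tumor-wide mean score exceeds 1.05 (gain) or falls
below 0.95 (loss) are signature events; at least three are required. The tumor
cell content of spot i for one event is

    gain:  C_i = (A_i - 1) / (max(A) - 1)
    loss:  C_i = (1 - A_i) / (1 - min(A))

with max/min over the tumor's spots in the event window; the per-spot content
is the average over events, clipped to [0, 1]. Spots with C > 0.2 are called
malignant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    """All spots were removed by QC."""


class InsufficientSignatureError(ValueError):
    """Fewer than the required number of signature CNA events qualify."""


@dataclass
class CNASpotProfile:
    """Per-spot windowed CNA scores.

    ``scores`` is a spot x window DataFrame centered at 1.0 after rescaling;
    ``window_meta`` records each window's chromosome and gene span;
    ``rescaled`` marks whether reference anchoring has been applied.
    """

    scores: pd.DataFrame
    window_meta: pd.DataFrame
    rescaled: bool = False


@dataclass
class SignatureEvent:
    """A windowed gain/loss shared across a tumor's spots."""

    window: str
    chromosome: int
    direction: str  # "gain" | "loss"
    mean_score: float


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_mito_frac: float = 0.05,
    min_spots_per_gene: int = 3,
) -> ad.AnnData:
    """Spot- then gene-level quality control.

    Removes spots with fewer than ``min_genes`` detected genes or a
    mitochondrial fraction strictly above ``max_mito_frac`` (a spot at exactly
    the threshold is retained), then genes detected in fewer than
    ``min_spots_per_gene`` of the remaining spots.
    """
    X = _dense(adata.X)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    if "is_mito" not in adata.var:
        raise ValueError("var must flag mitochondrial genes in 'is_mito'")
    detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    mito = X[:, adata.var["is_mito"].to_numpy(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    keep_spots = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    if not keep_spots.any():
        raise EmptyCohortError("QC removed every spot")
    out = adata[keep_spots].copy()
    gene_detected = (_dense(out.X) > 0).sum(axis=0)
    keep_genes = gene_detected >= min_spots_per_gene
    out = out[:, keep_genes].copy()
    log.info(
        "qc_filter: kept %d/%d spots, %d/%d genes",
        out.n_obs, adata.n_obs, out.n_vars, adata.n_vars,
    )
    return out


def _dense(X) -> np.ndarray:
    if hasattr(X, "toarray"):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def _log_cpm(X: np.ndarray) -> np.ndarray:
    totals = X.sum(axis=1, keepdims=True)
    cpm = X / np.maximum(totals, 1e-12) * 1e6
    return np.log1p(cpm)


def windowed_cna(
    tumor: ad.AnnData, reference: ad.AnnData, window: int = 100
) -> tuple[CNASpotProfile, CNASpotProfile]:
    """Windowed expression-ratio scores for tumor and reference spots.

    Genes are taken in the (chromosome-ordered) order of the shared gene set;
    windows are contiguous ``window``-gene blocks within each chromosome and
    partial trailing windows are dropped. Returns the unscaled tumor profile
    and the reference's own profile (needed for rescaling).
    """
    if reference.n_obs == 0:
        raise ValueError("reference is empty")
    shared = [g for g in tumor.var_names if g in set(reference.var_names)]
    if not shared:
        raise ValueError("no shared genes between tumor and reference")
    t = tumor[:, shared]
    r = reference[:, shared]
    if "chromosome" not in t.var:
        raise ValueError("var must carry a 'chromosome' column")
    if not np.array_equal(t.var["chromosome"].to_numpy(), r.var["chromosome"].to_numpy()):
        raise ValueError("gene order mismatch between tumor and reference")
    chrom = t.var["chromosome"].to_numpy()

    ref_log = _log_cpm(_dense(r.X))
    # reference per-gene profile: log1p of the mean CPM across reference spots
    ref_cpm_mean = np.expm1(ref_log).mean(axis=0)
    ref_gene = np.log1p(ref_cpm_mean)

    windows: list[tuple[str, int, int, int]] = []
    pos = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        n_full = len(idx) // window
        for w in range(n_full):
            lo, hi = idx[w * window], idx[w * window + window - 1]
            windows.append((f"chr{c}_w{w}", int(c), int(lo), int(hi)))
        pos += 1
    if not windows:
        raise ValueError(
            f"fewer than one full {window}-gene window on every chromosome"
        )

    def profile(X: np.ndarray) -> pd.DataFrame:
        logx = _log_cpm(X)
        diff = logx - ref_gene[None, :]
        # per-spot mean centering removes spot-level offsets (library depth
        # and count-noise bias) so only regional deviations remain
        diff -= diff.mean(axis=1, keepdims=True)
        cols = {}
        for name, c, lo, hi in windows:
            cols[name] = np.exp(diff[:, lo : hi + 1].mean(axis=1))
        return pd.DataFrame(cols)

    meta = pd.DataFrame(
        [(n, c, lo, hi) for n, c, lo, hi in windows],
        columns=["window", "chromosome", "gene_start", "gene_end"],
    ).set_index("window")
    tum_scores = profile(_dense(t.X))
    tum_scores.index = t.obs_names
    ref_scores = profile(_dense(r.X))
    ref_scores.index = r.obs_names
    return (
        CNASpotProfile(scores=tum_scores, window_meta=meta),
        CNASpotProfile(scores=ref_scores, window_meta=meta),
    )


def rescale_to_reference(
    profile: CNASpotProfile, reference_profile: CNASpotProfile
) -> CNASpotProfile:
    """Affine-anchor each window so reference spots span 0.98-1.02, mean 1.00.

    Per window the map sends the reference mean to 1.00 and the reference
    half-range (max - min)/2 to 0.02. A window with zero reference variance is
    shifted so its reference mean lands at 1.00 (flagged in logs).
    """
    ref = reference_profile.scores
    if ref.shape[0] < 2:
        raise ValueError("reference needs >= 2 spots per window")
    out = profile.scores.copy()
    flagged = []
    for w in out.columns:
        rv = ref[w].to_numpy()
        mean = rv.mean()
        half = (rv.max() - rv.min()) / 2.0
        if half <= 0:
            out[w] = out[w] - mean + 1.0
            flagged.append(w)
        else:
            out[w] = 1.0 + (out[w] - mean) * (0.02 / half)
    if flagged:
        log.warning("rescale_to_reference: zero-variance windows shifted: %s", flagged)
    return CNASpotProfile(scores=out, window_meta=profile.window_meta, rescaled=True)


def select_signature_events(
    profile: CNASpotProfile, min_events: int = 3
) -> list[SignatureEvent]:
    """Windows whose tumor-wide mean score is >1.05 (gain) or <0.95 (loss).

    Comparisons are strict; fewer than ``min_events`` qualifying windows raises
    :class:`InsufficientSignatureError`.
    """
    if not profile.rescaled:
        raise ValueError("profile must be rescaled before signature selection")
    means = profile.scores.mean(axis=0)
    events = []
    for w, m in means.items():
        if m > 1.05:
            events.append(
                SignatureEvent(w, int(profile.window_meta.loc[w, "chromosome"]), "gain", float(m))
            )
        elif m < 0.95:
            events.append(
                SignatureEvent(w, int(profile.window_meta.loc[w, "chromosome"]), "loss", float(m))
            )
    if len(events) < min_events:
        raise InsufficientSignatureError(
            f"only {len(events)} signature events (need >= {min_events})"
        )
    return events


def tumor_content(
    profile: CNASpotProfile, events: list[SignatureEvent]
) -> pd.Series:
    """Per-spot tumor cell content averaged over signature events.

    For each event the direction-specific formula is applied with the max/min
    taken over the tumor's spots in that event's window; degenerate events
    (extreme equal to 1) are skipped with a warning. The per-spot average is
    clipped to [0, 1].
    """
    if len(events) < 3:
        raise ValueError("need >= 3 signature events")
    per_event = []
    for ev in events:
        a = profile.scores[ev.window].to_numpy(float)
        if ev.direction == "gain":
            denom = a.max() - 1.0
            if denom <= 0:
                warnings.warn(f"degenerate gain event {ev.window} skipped")
                continue
            per_event.append((a - 1.0) / denom)
        else:
            denom = 1.0 - a.min()
            if denom <= 0:
                warnings.warn(f"degenerate loss event {ev.window} skipped")
                continue
            per_event.append((1.0 - a) / denom)
    if not per_event:
        raise ValueError("all signature events were degenerate")
    c = np.clip(np.mean(per_event, axis=0), 0.0, 1.0)
    return pd.Series(c, index=profile.scores.index, name="C")


def malignant_mask(content: pd.Series, threshold: float = 0.2) -> pd.Series:
    """Boolean malignant-spot mask: content strictly above ``threshold``."""
    c = content.to_numpy(float)
    if ((c < 0) | (c > 1)).any():
        raise ValueError("content must lie in [0, 1]")
    return pd.Series(c > threshold, index=content.index, name="malignant")


def estimate_content(
    tumor: ad.AnnData,
    reference: ad.AnnData,
    window: int = 100,
    min_events: int = 3,
) -> tuple[pd.Series, list[SignatureEvent], CNASpotProfile]:
    """Convenience composition: windowed scores -> rescale -> events -> content."""
    tum, ref = windowed_cna(tumor, reference, window=window)
    tum = rescale_to_reference(tum, ref)
    events = select_signature_events(tum, min_events=min_events)
    return tumor_content(tum, events), events, tum
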