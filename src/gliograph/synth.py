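"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Three generators:

* :func:`generate_label_map` — Potts-style lattice label maps whose same-class
  adjacency is controlled by ``clustering_strength`` (inverse temperature of
  seeded Gibbs sweeps, strength 0 giving i.i.d. labels);
* :func:`generate_expression_sample` — Visium-like spot count matrices with
  chromosome-ordered genes, embedded copy-number gains/losses scaled by a
  per-spot true tumor content, subtype-specific module up-regulation and
  mitochondrial-tagged genes for QC tests;
* :func:`generate_survival_cohort` — proportional-hazards event times with
  independent exponential censoring tuned by bisection to a target rate.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .graph import CellularMap

DEFAULT_CLASSES = ("AC-like", "MES-hypoxia", "MES-like", "NPC-like", "OPC-like")


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate one 10X-Visium-like sample: a 30x30 patch lattice, five
    transcriptional subtypes in equal proportion with moderate spatial
    clustering, 2000 genes in 8 equal chromosome blocks with gains on
    chromosomes 0-1 and losses on chromosomes 4-5 at 20% effect per unit tumor
    content, 30-gene subtype modules up-regulated two-fold, and exponential
    survival at ~30%% censoring.
    """

    n_samples: int = 1
    grid_width: int = 30
    grid_height: int = 30
    class_proportions: dict = field(
        default_factory=lambda: {c: 0.2 for c in DEFAULT_CLASSES}
    )
    clustering_strength: float = 1.0
    n_genes: int = 2000
    n_chromosomes: int = 8
    gain_chroms: tuple = (0, 1)
    loss_chroms: tuple = (4, 5)
    gain_effect: float = 0.2
    loss_effect: float = 0.2
    tumor_content_range: tuple = (0.0, 1.0)
    module_size: int = 30
    module_fold: float = 2.0
    n_mito_genes: int = 10
    nb_dispersion: float = 10.0
    n_ref_tissues: int = 6
    ref_pseudobulk: int = 20
    module_defs: dict | None = None
    survival_beta: dict = field(default_factory=dict)
    baseline_scale: float = 24.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if set(self.gain_chroms) & set(self.loss_chroms):
            raise ValueError("gain and loss chromosome sets must be disjoint")


@dataclass
class GroundTruth:
    """True per-spot quantities recorded alongside a generated sample."""

    content: np.ndarray
    subtype: np.ndarray
    module_defs: dict
    gain_chroms: tuple
    loss_chroms: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"true_content": self.content, "true_subtype": self.subtype}
        )


def generate_label_map(
    width: int,
    height: int,
    class_proportions: dict,
    clustering_strength: float = 0.0,
    seed: int = 0,
    n_sweeps: int = 20,
    sample_id: str = "sample",
) -> CellularMap:
    """Draw a lattice label map with tunable same-class adjacency.

    Labels start i.i.d. multinomial; for ``clustering_strength > 0`` we run
    ``n_sweeps`` Gibbs sweeps of an 8-neighbor Potts model at inverse
    temperature ``clustering_strength`` (conditional odds of class c are
    proportional to p_c * exp(strength * #same-class neighbors)). Updates use a
    four-color 2x2 block schedule, which is exact for the 8-neighborhood.
    """
    if width <= 0 or height <= 0:
        raise ValueError("grid dimensions must be positive")
    if not class_proportions:
        raise ValueError("empty class proportions")
    if clustering_strength < 0:
        raise ValueError("clustering_strength must be >= 0")
    props = {k: v for k, v in class_proportions.items() if v > 0}
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    classes = sorted(props)
    p = np.array([props[c] for c in classes], dtype=float)
    k = len(classes)
    rng = np.random.default_rng(seed)
    lab = rng.choice(k, size=(height, width), p=p)
    if clustering_strength > 0 and k > 1:
        logp = np.log(p)
        ys, xs = np.indices((height, width))
        offs = [
            (dx, dy)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0)
        ]
        for _ in range(n_sweeps):
            for cy in (0, 1):
                for cx in (0, 1):
                    onehot = (lab[None] == np.arange(k)[:, None, None]).astype(float)
                    pad = np.pad(onehot, ((0, 0), (1, 1), (1, 1)))
                    nbr = np.zeros((k, height, width))
                    for dx, dy in offs:
                        nbr += pad[:, 1 + dy : 1 + dy + height, 1 + dx : 1 + dx + width]
                    logits = logp[:, None, None] + clustering_strength * nbr
                    gum = rng.gumbel(size=(k, height, width))
                    new = np.argmax(logits + gum, axis=0)
                    mask = (ys % 2 == cy) & (xs % 2 == cx)
                    lab[mask] = new[mask]
    labels = np.array(classes, dtype=object)[lab]
    return CellularMap(labels=labels, sample_id=sample_id)


def generate_label_maps_batch(
    n_maps: int,
    width: int,
    height: int,
    class_proportions: dict,
    clustering_strengths,
    seed: int = 0,
    n_sweeps: int = 20,
) -> np.ndarray:
    """Draw many label maps at once (one clustering strength per map).

    Same Potts dynamics as :func:`generate_label_map`, batched over maps for
    cohort simulation; returns an object array of shape (n_maps, height,
    width). Strength 0 maps still go through the (no-op-free) sweeps, so a
    zero-strength map from this path matches the i.i.d. distribution but not
    the bitstream of a single :func:`generate_label_map` call.
    """
    props = {k: v for k, v in class_proportions.items() if v > 0}
    classes = sorted(props)
    p = np.array([props[c] for c in classes], dtype=float)
    k = len(classes)
    strengths = np.asarray(clustering_strengths, dtype=float).reshape(n_maps)
    rng = np.random.default_rng(seed)
    lab = rng.choice(k, size=(n_maps, height, width), p=p)
    if k > 1 and (strengths > 0).any():
        logp = np.log(p)
        ys, xs = np.indices((height, width))
        offs = [
            (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
        ]
        st = strengths[:, None, None, None]
        for _ in range(n_sweeps):
            for cy in (0, 1):
                for cx in (0, 1):
                    onehot = (
                        lab[:, None] == np.arange(k)[None, :, None, None]
                    ).astype(float)
                    pad = np.pad(onehot, ((0, 0), (0, 0), (1, 1), (1, 1)))
                    nbr = np.zeros((n_maps, k, height, width))
                    for dx, dy in offs:
                        nbr += pad[
                            :, :, 1 + dy : 1 + dy + height, 1 + dx : 1 + dx + width
                        ]
                    logits = logp[None, :, None, None] + st * nbr
                    gum = rng.gumbel(size=(n_maps, k, height, width))
                    new = np.argmax(logits + gum, axis=1)
                    mask = (ys % 2 == cy) & (xs % 2 == cx)
                    lab[:, mask] = new[:, mask]
    return np.array(classes, dtype=object)[lab]


def default_module_defs(config: SynthConfig) -> dict:
    """Deterministic subtype -> gene-name modules on CNA-neutral chromosomes.

    Module genes are interleaved across the neutral chromosomes (stride equal
    to the number of classes) rather than laid out as contiguous blocks:
    subtype expression programs are scattered through the genome, so no single
    CNA window is dominated by one module.
    """
    neutral = [
        c
        for c in range(config.n_chromosomes)
        if c not in config.gain_chroms and c not in config.loss_chroms
    ]
    if not neutral:
        neutral = list(range(config.n_chromosomes))
    block = config.n_genes // config.n_chromosomes
    classes = sorted(config.class_proportions)
    n_cls = len(classes)
    per_chrom = -(-config.module_size // len(neutral))  # ceil
    spread = max(1, (block - config.n_mito_genes) // (n_cls * per_chrom))
    defs: dict[str, list[str]] = {}
    for i, cls in enumerate(classes):
        idx = []
        j = 0
        while len(idx) < config.module_size:
            chrom = neutral[j % len(neutral)]
            slot = i + n_cls * spread * (j // len(neutral))
            g = chrom * block + slot
            if slot >= block - config.n_mito_genes:
                raise ValueError("modules do not fit on the neutral chromosomes")
            idx.append(g)
            j += 1
        defs[cls] = [f"gene_{k}" for k in sorted(idx)]
    return defs


def _gene_model(config: SynthConfig):
    """Deterministic gene model shared between tumor and reference samples.

    Derived from ``config.seed`` only, so tumor and normal samples of the same
    study share one "genome": gene names, chromosome layout, per-gene baseline
    means and the mitochondrial tags. Mito genes occupy the tail of the last
    CNA-neutral chromosome (clear of the subtype modules, which sit at the
    head of neutral chromosomes).
    """
    block = config.n_genes // config.n_chromosomes
    if block < 1:
        raise ValueError("n_genes too small for the number of chromosomes")
    rng = np.random.default_rng(config.seed)
    chrom = np.repeat(np.arange(config.n_chromosomes), block)
    chrom = np.concatenate(
        [chrom, np.full(config.n_genes - chrom.size, config.n_chromosomes - 1)]
    )
    base = rng.lognormal(mean=2.5, sigma=0.6, size=config.n_genes)
    genes = np.array([f"gene_{i}" for i in range(config.n_genes)], dtype=object)
    neutral = [
        c
        for c in range(config.n_chromosomes)
        if c not in config.gain_chroms and c not in config.loss_chroms
    ] or [config.n_chromosomes - 1]
    last = neutral[-1]
    hi = int(np.flatnonzero(chrom == last).max()) + 1
    mito_idx = np.arange(hi - config.n_mito_genes, hi)
    is_mito = np.zeros(config.n_genes, dtype=bool)
    is_mito[mito_idx] = True
    genes[mito_idx] = [f"MT-{j}" for j in range(len(mito_idx))]
    return genes, chrom, base, is_mito


def generate_expression_sample(
    config: SynthConfig, seed: int | None = None
) -> tuple[ad.AnnData, GroundTruth]:
    """Generate one spot-level expression sample with planted CNA structure.

    Genes ``gene_0..gene_{n-1}`` occupy contiguous equal-size chromosome blocks
    in index order; the per-gene baseline is fixed by ``config.seed`` (shared
    with the matching reference). Counts are negative binomial; for a spot
    with true content ``c`` the means of genes on gained chromosomes scale by
    ``(1 + c*gain_effect)`` and lost ones by ``(1 - c*loss_effect)``. Module
    genes are up-scaled ``module_fold``-fold in spots of the matching subtype.
    The tail of the last neutral chromosome carries ``MT-*`` flagged genes.
    """
    if seed is None:
        seed = config.seed
    genes, chrom, base, is_mito = _gene_model(config)
    rng = np.random.default_rng(seed)
    cmap = generate_label_map(
        config.grid_width,
        config.grid_height,
        config.class_proportions,
        config.clustering_strength,
        seed=int(rng.integers(2**31)),
    )
    subtype = cmap.labels.ravel().astype(str)
    n_spots = subtype.size
    lo, hi = config.tumor_content_range
    content = rng.uniform(lo, hi, size=n_spots)

    module_defs = (
        config.module_defs
        if config.module_defs is not None
        else default_module_defs(config)
    )
    gene_index = {g: i for i, g in enumerate(genes)}

    scale = np.ones((n_spots, config.n_genes))
    gain_mask = np.isin(chrom, config.gain_chroms)
    loss_mask = np.isin(chrom, config.loss_chroms)
    scale[:, gain_mask] *= 1.0 + content[:, None] * config.gain_effect
    scale[:, loss_mask] *= 1.0 - content[:, None] * config.loss_effect
    for cls, mod_genes in module_defs.items():
        idx = [gene_index[g] for g in mod_genes if g in gene_index]
        spots = np.flatnonzero(subtype == cls)
        if idx and spots.size:
            scale[np.ix_(spots, idx)] *= config.module_fold

    libsize = rng.lognormal(mean=0.0, sigma=0.2, size=n_spots)
    mu = base[None, :] * scale * libsize[:, None]
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int32)

    ys, xs = np.indices(cmap.labels.shape)
    obs = pd.DataFrame(
        {
            "x": xs.ravel(),
            "y": ys.ravel(),
            "true_content": content,
            "true_subtype": subtype,
        },
        index=[f"spot_{i}" for i in range(n_spots)],
    )
    var = pd.DataFrame({"chromosome": chrom, "is_mito": is_mito}, index=genes.astype(str))
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["module_defs"] = {k: list(v) for k, v in module_defs.items()}
    truth = GroundTruth(
        content=content,
        subtype=subtype,
        module_defs=module_defs,
        gain_chroms=tuple(config.gain_chroms),
        loss_chroms=tuple(config.loss_chroms),
    )
    return adata, truth


def generate_reference_sample(config: SynthConfig, seed: int) -> ad.AnnData:
    """Normal-brain reference: a few pseudo-bulk tissue profiles.

    Shares the tumor's gene model (same ``config.seed``), has zero tumor
    content and no module structure. Each of ``n_ref_tissues`` rows aggregates
    ``ref_pseudobulk`` spot-equivalents — NB(k*mu, k*r) — emulating tissue-
    level normal-brain transcriptomes, whose window scores are far less noisy
    than single spots.
    """
    genes, chrom, base, is_mito = _gene_model(config)
    rng = np.random.default_rng(seed)
    k = config.ref_pseudobulk
    n = config.n_ref_tissues
    libsize = rng.lognormal(mean=0.0, sigma=0.1, size=n)
    mu = k * base[None, :] * libsize[:, None]
    r = k * config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    obs = pd.DataFrame(index=[f"ref_{i}" for i in range(n)])
    var = pd.DataFrame({"chromosome": chrom, "is_mito": is_mito}, index=genes.astype(str))
    return ad.AnnData(X=counts, obs=obs, var=var)


def generate_survival_cohort(
    sample_features: pd.DataFrame,
    beta: dict,
    baseline_scale: float = 24.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportional-hazards survival for a cohort with given features.

    Event times are exponential with rate ``exp(x.beta) / baseline_scale``;
    censoring is an independent exponential whose rate is tuned by bisection so
    the expected censored fraction matches ``censor_rate`` within 0.02.

    Returns a table with ``patient_id``, ``time``, ``event`` and the feature
    columns.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    X = sample_features
    if not np.isfinite(X.to_numpy(float)).all():
        raise ValueError("features must be finite")
    rng = np.random.default_rng(seed)
    n = len(X)
    eta = np.zeros(n)
    for name, b in beta.items():
        eta += b * X[name].to_numpy(float)
    rate = np.exp(eta) / baseline_scale
    t_event = rng.exponential(1.0 / rate)

    if censor_rate == 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        # expected censored fraction under Exp(mu) censoring given event times
        def frac(mu: float) -> float:
            return float(np.mean(1.0 - np.exp(-mu * t_event)))

        lo_mu, hi_mu = 1e-12, 1.0 / max(t_event.min(), 1e-12)
        while frac(hi_mu) < censor_rate:
            hi_mu *= 2.0
        for _ in range(200):
            mid = 0.5 * (lo_mu + hi_mu)
            if frac(mid) < censor_rate:
                lo_mu = mid
            else:
                hi_mu = mid
            if abs(frac(mid) - censor_rate) < 1e-4:
                break
        mu = 0.5 * (lo_mu + hi_mu)
        t_cens = rng.exponential(1.0 / mu, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

    out = pd.DataFrame(
        {"patient_id": [f"pt_{i:04d}" for i in range(n)], "time": time, "event": event}
    )
    return pd.concat([out, X.reset_index(drop=True)], axis=1)
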