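"""Cohort-level orchestration: filters, per-patient aggregation, survival
association of compositions and architecture, differential expression between
aggressiveness groups, and gene-set enrichment.

``run_pipeline`` composes the full flow on a synthetic cohort: simulate ->
QC -> CNA content -> malignant filter -> subtype assignment -> graph features
-> survival association -> risk-model training and composite-score evaluation
-> DE and enrichment, writing every artifact plus a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import cna, graph, io, scoring, survival, synth

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def filter_small_tumors(
    cohort: pd.DataFrame,
    frac: float = 0.05,
    patch_col: str = "n_patches",
    id_col: str = "patient_id",
) -> pd.DataFrame:
    """Drop the floor(frac*N) tumors with the fewest patches.

    Ties at the cutoff break on patient id (lexicographically smaller removed
    first), logged for reproducibility.
    """
    if frac >= 1:
        raise ValueError("frac must be < 1")
    n_drop = int(np.floor(frac * len(cohort)))
    if n_drop == 0:
        return cohort.copy()
    ranked = cohort.sort_values([patch_col, id_col], kind="stable")
    dropped = ranked.iloc[:n_drop]
    log.info("filter_small_tumors: removed %s", list(dropped[id_col]))
    return ranked.iloc[n_drop:].sort_index()


def patient_risk(patch_scores_by_patient: dict[str, np.ndarray]) -> pd.Series:
    """Mean aggressive score over all of a patient's patches, slides pooled."""
    out = {}
    for pid, patches in patch_scores_by_patient.items():
        if isinstance(patches, (list, tuple)):
            parts = [np.atleast_1d(np.asarray(p, float)) for p in patches]
            arr = np.concatenate(parts) if parts else np.empty(0)
        else:
            arr = np.asarray(patches, float).ravel()
        if arr.size == 0:
            raise ValueError(f"patient {pid!r} has no patches")
        out[pid] = float(arr.mean())
    return pd.Series(out, name="risk")


def minmax_by_sample(scores: pd.Series, sample_ids: pd.Series) -> pd.Series:
    """Min-max normalize scores within each sample to [0, 1]."""
    out = scores.astype(float).copy()
    for sid, idx in scores.groupby(sample_ids).groups.items():
        v = scores.loc[idx].astype(float)
        span = v.max() - v.min()
        if span == 0:
            raise ValueError(f"sample {sid!r} has constant scores")
        out.loc[idx] = (v - v.min()) / span
    return out


def multivariate_cox_association(
    cohort: pd.DataFrame,
    feature_block: list[str],
    covariates: list[str] = ("gender", "age", "IDH", "n_patches"),
    time_col: str = "time",
    event_col: str = "event",
    drop_reference: str | None = None,
    standardize: bool = True,
    l2: float = 0.0,
) -> pd.DataFrame:
    """One multivariate Cox fit for a feature block plus clinical covariates.

    Continuous columns are z-scored (HRs are per-SD); a reference category can
    be dropped from compositional blocks; constant columns are dropped with a
    warning. Returns HR/CI/p per block feature with BH-adjusted q across the
    block only.
    """
    block = [f for f in feature_block if f != drop_reference]
    if drop_reference is not None:
        log.info("dropping reference category %r from block", drop_reference)
    cols = list(block) + [c for c in covariates if c in cohort.columns]
    work = cohort[cols + [time_col, event_col]].copy()
    finite = np.isfinite(work[cols].to_numpy(float)).all(axis=1)
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} rows with missing features")
        work = work.loc[finite]
    kept = []
    for c in cols:
        v = work[c].to_numpy(float)
        if np.ptp(v) == 0:
            warnings.warn(f"feature {c!r} is constant; dropped")
            continue
        if standardize and np.unique(v).size > 2:
            work[c] = (v - v.mean()) / v.std()
        kept.append(c)
    block_kept = [c for c in block if c in kept]
    if not block_kept:
        raise ValueError("no usable features in block")
    fit = survival.fit_linear_cox(
        work, covariates=kept, time_col=time_col, event_col=event_col, l2=l2
    )
    rep = fit.summary().loc[block_kept].copy()
    rep["q"] = multipletests(rep["p"], method="fdr_bh")[1]
    rep.attrs["converged"] = fit.converged
    return rep


def de_between_groups(
    counts: np.ndarray,
    gene_names: list[str],
    group_labels: np.ndarray,
    lfc_min: float = 0.25,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Rank-sum differential expression between high/low aggressiveness spots.

    Counts (spots x genes) are normalized to counts-per-10k; the two-sided
    Mann-Whitney test runs per gene and log2FC = log2((mean_high + eps) /
    (mean_low + eps)) on the normalized values. ``significant`` marks genes
    with |log2FC| > lfc_min (strict) and p < p_max, per direction.
    """
    X = np.asarray(counts, dtype=float)
    labels = np.asarray(group_labels)
    hi = labels == "high"
    lo = labels == "low"
    if hi.sum() < 20 or lo.sum() < 20:
        raise ValueError("both groups need >= 20 spots")
    norm = X / np.maximum(X.sum(axis=1, keepdims=True), 1e-12) * 1e4
    eps = 1e-9
    mean_hi = norm[hi].mean(axis=0)
    mean_lo = norm[lo].mean(axis=0)
    lfc = np.log2((mean_hi + eps) / (mean_lo + eps))
    with np.errstate(all="ignore"):
        res = stats.mannwhitneyu(norm[hi], norm[lo], axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # all-tied genes are untestable
    out = pd.DataFrame({"gene": gene_names, "log2fc": lfc, "p": p})
    out["direction"] = np.where(lfc > 0, "high", "low")
    out["significant"] = (np.abs(lfc) > lfc_min) & (p < p_max)
    return out


def hypergeom_enrichment(
    hit_genes: set,
    gene_sets: dict[str, set],
    universe: set,
    p_max: float = 0.05,
    q_max: float = 0.20,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of gene sets in a hit list.

    BH q-values across sets; ``enriched`` marks sets with p < p_max and
    q < q_max.
    """
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes) & set(universe)
    N = len(universe)
    K = len(hits)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(universe)
        n = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"set": name, "set_size": n, "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["p"] < p_max) & (out["q"] < q_max)
    return out


# ---------------------------------------------------------------------------
# Cohort simulation helpers and the end-to-end run


def simulate_patient_cohort(
    n_patients: int,
    grid: tuple[int, int] = (20, 20),
    class_proportions: dict | None = None,
    strength_range: tuple[float, float] = (0.0, 0.8),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient cellular maps -> slide feature vectors.

    Each patient gets one label map at a patient-specific clustering strength
    (uniform in ``strength_range``), so architecture features vary across the
    cohort. Returns one row per patient with proportions, clustering
    coefficients, interaction fractions and ``n_patches``.
    """
    props = class_proportions or {c: 0.2 for c in synth.DEFAULT_CLASSES}
    rng = np.random.default_rng(seed)
    strengths = rng.uniform(*strength_range, size=n_patients)
    maps = synth.generate_label_maps_batch(
        n_patients, grid[0], grid[1], props, strengths, seed=int(rng.integers(2**31))
    )
    rows = []
    for i in range(n_patients):
        feats = graph.lattice_features(maps[i])
        feats["n_patches"] = grid[0] * grid[1]
        feats.name = f"pt_{i:04d}"
        rows.append(feats)
    df = pd.DataFrame(rows)
    df.index.name = "patient_id"
    return df


def attach_clinical_covariates(features: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Add synthetic gender/age/IDH covariates (0/1 indicators, age in years)."""
    rng = np.random.default_rng(seed)
    out = features.copy()
    n = len(out)
    out["gender"] = rng.integers(0, 2, size=n)
    out["age"] = rng.normal(60.0, 10.0, size=n).round(1)
    out["IDH"] = (rng.random(n) < 0.1).astype(int)
    return out


def recovery_simulation(
    n_reps: int = 100,
    n_patients: int = 300,
    log_hr: float = 1.0,
    feature: str = "cc_AC-like",
    grid: tuple[int, int] = (16, 16),
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted architecture-effect recovery across seeded replicate cohorts.

    Each replicate simulates ``n_patients`` cellular maps, plants a hazard of
    ``log_hr`` per SD of the chosen architecture feature, fits the multivariate
    association model (clustering-coefficient block with proportion and
    clinical covariates) and records the fitted log-HR, its 95% CI coverage of
    the truth and its sign.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        s = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3)]
        feats = simulate_patient_cohort(n_patients, grid=grid, seed=s[0])
        feats = attach_clinical_covariates(feats, seed=s[1])
        ok = np.isfinite(feats[feature].to_numpy(float))
        feats = feats.loc[ok]
        z = feats[[feature]].copy()
        v = z[feature].to_numpy(float)
        z[feature] = (v - v.mean()) / v.std()
        table = synth.generate_survival_cohort(
            z, {feature: log_hr}, 24.0, censor_rate, seed=s[2]
        )
        table.index = feats.index
        cohort = pd.concat([feats, table[["time", "event"]]], axis=1)
        cc_cols = sorted(c for c in cohort.columns if c.startswith("cc_"))
        prop_cols = sorted(c for c in cohort.columns if c.startswith("prop_"))
        rep_table = multivariate_cox_association(
            cohort,
            feature_block=cc_cols,
            covariates=prop_cols[1:] + ["gender", "age", "IDH"],
        )
        b = float(rep_table.loc[feature, "beta"])
        se = float(rep_table.loc[feature, "se"])
        rows.append(
            {
                "rep": rep,
                "beta_hat": b,
                "se": se,
                "covered": abs(b - log_hr) <= 1.959963984540054 * se,
                "positive": b > 0,
            }
        )
    return pd.DataFrame(rows)


def null_association_simulation(
    n_reps: int = 40, n_patients: int = 120, seed: int = 0
) -> pd.DataFrame:
    """Replicate association runs with no planted effect (FDR calibration)."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_reps)):
        s = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3)]
        feats = simulate_patient_cohort(n_patients, grid=(14, 14), seed=s[0])
        feats = attach_clinical_covariates(feats, seed=s[1])
        table = synth.generate_survival_cohort(
            feats[["age"]] * 0.0, {}, 24.0, 0.3, seed=s[2]
        )
        table.index = feats.index
        cohort = pd.concat([feats, table[["time", "event"]]], axis=1)
        cc_cols = sorted(c for c in cohort.columns if c.startswith("cc_"))
        prop_cols = sorted(c for c in cohort.columns if c.startswith("prop_"))
        rep_table = multivariate_cox_association(
            cohort,
            feature_block=cc_cols,
            covariates=prop_cols[1:] + ["gender", "age", "IDH"],
        )
        rows.append(
            {"rep": rep, "n_bh_significant": int((rep_table["q"] < 0.05).sum())}
        )
    return pd.DataFrame(rows)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 -- surface with stage name
                raise PipelineStageError(name, e) from e

        return wrapper

    return deco


def run_pipeline(config: synth.SynthConfig | None = None, outdir=".", seed: int = 0) -> dict:
    """Run the full synthetic-cohort analysis and write a manifest.

    Stages: simulate (tumor + reference expression, patient cohort) -> QC ->
    CNA content -> malignant filter -> module scoring and subtype assignment
    -> graph features -> survival association -> patch-level risk network with
    composite-score evaluation and median-split log-rank -> DE between
    aggressiveness groups -> enrichment. Deterministic per seed; re-runs are
    byte-identical.
    """
    cfg = config or synth.SynthConfig(seed=seed)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(12)]
    manifest: dict = {"seed": seed, "stages": {}, "files": []}

    def record(name: str, path: pathlib.Path, **summary):
        manifest["files"].append(str(path.relative_to(outdir)))
        manifest["stages"].setdefault(name, {}).update(summary)

    # --- simulate -----------------------------------------------------------
    @_stage("simulate")
    def do_sim():
        adata, truth = synth.generate_expression_sample(cfg, seed=seeds[0])
        ref = synth.generate_reference_sample(cfg, seed=seeds[1])
        io.write_expression_mtx(adata, outdir / "expression")
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
        io.write_module_defs(truth.module_defs, outdir / "modules.csv")
        return adata, truth, ref

    adata, truth, ref = do_sim()
    record("simulate", outdir / "expression" / "matrix.mtx", n_spots=int(adata.n_obs))
    record("simulate", outdir / "ground_truth.csv")
    record("simulate", outdir / "modules.csv")

    # --- QC -----------------------------------------------------------------
    @_stage("qc")
    def do_qc():
        # generator spots are deep; QC here guards degenerate inputs
        return cna.qc_filter(adata, min_genes=min(200, adata.n_vars // 2))

    filtered = do_qc()
    manifest["stages"]["qc"] = {"n_spots": int(filtered.n_obs), "n_genes": int(filtered.n_vars)}

    # --- CNA content --------------------------------------------------------
    @_stage("cna_content")
    def do_cna():
        content, events, profile = cna.estimate_content(filtered, ref)
        df = pd.DataFrame({"spot_id": content.index, "C": content.to_numpy()})
        df["n_events"] = len(events)
        df.to_csv(outdir / "tumor_content.csv", index=False)
        profile.scores.to_csv(outdir / "cna_windows.csv")
        return content, events

    content, events = do_cna()
    record("cna_content", outdir / "tumor_content.csv", n_events=len(events))
    record("cna_content", outdir / "cna_windows.csv")

    # --- malignant filter ---------------------------------------------------
    mask = cna.malignant_mask(content)
    malignant = filtered[mask.to_numpy()].copy()
    manifest["stages"]["malignant_filter"] = {"n_malignant": int(malignant.n_obs)}

    # --- subtype assignment -------------------------------------------------
    @_stage("subtype")
    def do_subtype():
        scores = scoring.score_modules(malignant, truth.module_defs, seed=seeds[2])
        labels = scoring.assign_subtypes(scores)
        scores.rename_axis("spot_id").to_csv(outdir / "module_scores.csv")
        labels.rename_axis("spot_id").to_frame().to_csv(outdir / "subtypes.csv")
        acc = float(
            (labels.to_numpy() == malignant.obs["true_subtype"].to_numpy()).mean()
        )
        return labels, acc

    labels, subtype_acc = do_subtype()
    record("subtype", outdir / "module_scores.csv", accuracy=round(subtype_acc, 4))
    record("subtype", outdir / "subtypes.csv")

    # --- graph features of the assigned map ---------------------------------
    @_stage("graph_features")
    def do_graph():
        frame = malignant.obs[["x", "y"]].copy()
        frame["label"] = labels.to_numpy()
        # malignant spots form a partial lattice; build the graph directly
        G = graph.nx_from_frame(frame)
        feats = graph.slide_features(G)
        feats.rename_axis("feature").to_frame("value").to_csv(outdir / "slide_features.csv")
        graph.export_graphml(G, outdir / "neighborhood.graphml")
        return feats

    slide_feats = do_graph()
    record("graph_features", outdir / "slide_features.csv")
    record("graph_features", outdir / "neighborhood.graphml")

    # --- patient cohort + survival association ------------------------------
    @_stage("survival_association")
    def do_assoc():
        feats = simulate_patient_cohort(120, seed=seeds[3])
        feats = attach_clinical_covariates(feats, seed=seeds[4])
        feats = filter_small_tumors(feats.reset_index(), frac=0.05).set_index("patient_id")
        beta = dict(cfg.survival_beta) or {"cc_AC-like": 1.0}
        ok = np.isfinite(feats[list(beta)].to_numpy(float)).all(axis=1)
        feats = feats.loc[ok]
        zfeats = feats[list(beta)].copy()
        for k in beta:
            v = zfeats[k].to_numpy(float)
            zfeats[k] = (v - v.mean()) / v.std()
        table = synth.generate_survival_cohort(
            zfeats, beta, cfg.baseline_scale, cfg.censor_rate, seed=seeds[5]
        )
        table.index = feats.index
        cc_cols = [c for c in feats.columns if c.startswith("cc_")]
        prop_cols = sorted(c for c in feats.columns if c.startswith("prop_"))
        cohort = pd.concat([feats, table[["time", "event"]]], axis=1)
        rep = multivariate_cox_association(
            cohort,
            feature_block=cc_cols,
            covariates=prop_cols[1:] + ["gender", "age", "IDH", "n_patches"],
        )
        rep.rename_axis("feature").to_csv(outdir / "association.csv")
        io.write_survival(table, outdir / "survival.csv")
        return cohort, rep

    cohort, assoc = do_assoc()
    record("survival_association", outdir / "association.csv",
           top_feature=str(assoc["q"].idxmin()), top_q=float(assoc["q"].min()))
    record("survival_association", outdir / "survival.csv")

    # --- risk model ---------------------------------------------------------
    @_stage("risk_model")
    def do_risk():
        feat_cols = [c for c in cohort.columns
                     if c.startswith(("prop_", "cc_", "int_")) and cohort[c].notna().all()]
        work = cohort.dropna(axis=1)
        n = len(work)
        rng = np.random.default_rng(seeds[6])
        perm = rng.permutation(n)
        split = int(0.7 * n)
        train, test = work.iloc[perm[:split]], work.iloc[perm[split:]]
        model = survival.fit_risk_network(
            train, feat_cols, hidden_sizes=(), epochs=300, seed=seeds[7]
        )
        scores = pd.Series(model.predict(test[feat_cols]), index=test.index)
        ev = survival.evaluate_risk_scores(scores, test["time"], test["event"])
        groups = survival.median_split(scores)
        stat, p = survival.logrank(test[groups == "high"], test[groups == "low"])
        model.to_json(outdir / "risk_model.json")
        pd.DataFrame({"patient_id": scores.index, "score": scores.to_numpy(),
                      "group": groups.to_numpy()}).to_csv(outdir / "risk_scores.csv", index=False)
        return ev, p

    risk_eval, logrank_p = do_risk()
    record("risk_model", outdir / "risk_model.json",
           cs=round(risk_eval["cs"], 4), cindex=round(risk_eval["cindex"], 4),
           ibs=round(risk_eval["ibs"], 4), logrank_p=float(logrank_p))
    record("risk_model", outdir / "risk_scores.csv")

    # --- DE + enrichment ----------------------------------------------------
    @_stage("de_enrichment")
    def do_de():
        # spot-level aggressiveness proxy: module-score-weighted risk ordering
        # (MES-hypoxia high, OPC-like low), split at the cohort median
        scores = scoring.score_modules(malignant, truth.module_defs, seed=seeds[8])
        spot_risk = scores["MES-hypoxia"] - scores["OPC-like"] \
            if {"MES-hypoxia", "OPC-like"} <= set(scores.columns) \
            else scores.iloc[:, 0]
        groups = survival.median_split(spot_risk)
        X = malignant.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        de = de_between_groups(np.asarray(X), list(malignant.var_names), groups.to_numpy())
        de.to_csv(outdir / "de_genes.csv", index=False)
        hits = set(de.loc[de["significant"] & (de["direction"] == "high"), "gene"])
        gene_sets = {f"module:{m}": set(g) for m, g in truth.module_defs.items()}
        enr = hypergeom_enrichment(hits, gene_sets, set(malignant.var_names))
        enr.to_csv(outdir / "enrichment.csv", index=False)
        return de, enr

    de, enr = do_de()
    record("de_enrichment", outdir / "de_genes.csv",
           n_significant=int(de["significant"].sum()))
    record("de_enrichment", outdir / "enrichment.csv",
           enriched_sets=enr.loc[enr["enriched"], "set"].tolist())

    manifest["files"] = sorted(manifest["files"])
    payload = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["digest"] = hashlib.sha256(payload.encode()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
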