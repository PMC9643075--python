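"""End-to-end orchestration: traits → λ → P/S decomposition → risk models.

The full analysis for one taxon runs in fixed stage order: align the
tree and trait table to their common species, (optionally) derive
morphometric traits from specimen images, screen predictors for
multicollinearity, estimate Pagel's λ per trait, decompose each trait
into P- and S-components under the phylogenetic mixed model, and fit
three proportional-odds blocks (S-components, P-components, raw traits)
against the ordinal red-list status.  :func:`analyze` is the in-memory
core; :func:`run_pipeline` adds file IO and provenance.  Outputs are
plain CSV tables plus a JSON report with seed, config hash, package
version and input checksums.  The pipeline is deterministic given its
inputs, and all results are computed before anything is written, so a
failing stage leaves no partial output behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lynch import decompose_all, variance_components_table
from .morphometrics import DEFAULT_DPI, morphometric_table
from .ordinal import STATUS_SCALE, encode_status, fit_trait_block
from .ranges import DEFAULT_CORR_THRESHOLD, vif_screen
from .signal import PhyloCovariance, estimate_lambda, phylo_covariance
from .synthetic import STUDY_TRAITS, read_specimen
from .trees import prune_tree, read_tree, tip_labels

__all__ = ["PipelineConfig", "AnalysisReport", "align_inputs", "analyze",
           "run_pipeline"]

log = logging.getLogger("phylorisk")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (mirrors the CLI flags)."""

    tree: str = ""
    traits: str = ""
    images: str | None = None
    dpi: float = DEFAULT_DPI
    status_col: str = "status"
    trait_cols: tuple = STUDY_TRAITS
    log_traits: bool = False
    joint: bool = True
    include_wings: bool = True
    vif_threshold: float = DEFAULT_CORR_THRESHOLD
    # only decompose traits whose λ is significant when True; the
    # default decomposes every model trait, since the final risk models
    # include all traits in both components
    gate_on_signal: bool = False
    gate_alpha: float = 0.05
    seed: int = 0
    out: str = "phylorisk_out"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Read a flat ``key = value`` config file."""
        valid = set(cls.__dataclass_fields__)
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, float):
                kwargs[key] = float(value)
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, tuple):
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    lambda_table: pd.DataFrame
    variance_components: pd.DataFrame
    blocks: dict  # {"S": DataFrame, "P": DataFrame, "raw": DataFrame}
    block_fits: dict  # same keys, OrdinalFitResult (or dict per trait)
    decomposition: pd.DataFrame  # species × (trait_P, trait_S) columns
    dropped: list
    vif_excluded: list
    provenance: dict


def _encode_status_column(values: pd.Series):
    """Map a status column to 0–4; return (encoded, bad) keeping order."""
    encoded, bad = {}, []
    for sp, v in values.items():
        if isinstance(v, (int, np.integer)) or (
                isinstance(v, str) and v.strip().isdigit()):
            iv = int(v)
            if 0 <= iv <= len(STATUS_SCALE) - 1:
                encoded[sp] = iv
            else:
                bad.append((sp, v))
            continue
        try:
            encoded[sp] = encode_status(v)
        except (ValueError, TypeError):
            bad.append((sp, v))
    return pd.Series(encoded, dtype=int), bad


def align_inputs(tree, table: pd.DataFrame, *,
                 status_col: str = "status",
                 trait_cols=None):
    """Restrict the analysis to species with tree tip, traits and status.

    Returns ``(pruned_tree, aligned_table, dropped)`` where ``dropped``
    lists (species, reason) pairs; every drop is logged.  The pruned
    tree preserves all pairwise root-to-MRCA depths among survivors.
    """
    tips = set(tip_labels(tree))
    dropped: list[tuple[str, str]] = []

    keep = []
    for sp in table.index:
        if sp not in tips:
            dropped.append((sp, "missing tree tip"))
            continue
        keep.append(sp)
    for tip in sorted(tips - set(table.index)):
        dropped.append((tip, "missing trait row"))

    sub = table.loc[keep]
    if trait_cols:
        na = sub[list(trait_cols)].isna()
        for sp in sub.index[na.any(axis=1)]:
            cols = list(na.columns[na.loc[sp]])
            dropped.append((sp, f"missing trait value(s): {cols}"))
        sub = sub.loc[~na.any(axis=1)]
    if status_col is not None and status_col in sub.columns:
        enc, bad = _encode_status_column(sub[status_col])
        for sp, v in bad:
            dropped.append((sp, f"unsupported red-list code {v!r}"))
        sub = sub.loc[enc.index].copy()
        sub[status_col] = enc

    if sub.empty:
        raise ValueError("no species shared between tree and trait table")
    for sp, reason in dropped:
        log.info("dropped %s: %s", sp, reason)
    pruned = tree if len(sub) == len(tips) else prune_tree(tree, sub.index)
    return pruned, sub, dropped


def analyze(tree_or_cov, table: pd.DataFrame,
            config: PipelineConfig | None = None) -> AnalysisReport:
    """Run the statistical stages on an already-aligned data set.

    ``table`` must contain the configured trait columns plus the
    (already encoded or encodable) status column, with species ids as
    index matching the tree's tips exactly.
    """
    cfg = config or PipelineConfig()
    stage = "align"
    try:
        cov = (tree_or_cov if isinstance(tree_or_cov, PhyloCovariance)
               else phylo_covariance(tree_or_cov))
        trait_cols = [c for c in cfg.trait_cols if c in table.columns]
        missing = set(cfg.trait_cols) - set(trait_cols)
        if missing:
            raise ValueError(f"trait column(s) absent: {sorted(missing)}")
        if set(table.index) != set(cov.taxa):
            raise ValueError("table species do not match tree tips; "
                             "call align_inputs first")
        table = table.loc[list(cov.taxa)]
        enc, bad = _encode_status_column(table[cfg.status_col])
        if bad:
            raise ValueError(f"unsupported red-list codes: {bad[:5]}")
        status = enc.loc[table.index]

        stage = "vif screen"
        candidates = [c for c in table.columns
                      if c != cfg.status_col
                      and pd.api.types.is_numeric_dtype(table[c])]
        retained, vif_excluded = vif_screen(table[candidates],
                                            cfg.vif_threshold)
        for rec in vif_excluded:
            log.info("vif_screen excluded %s (|r|=%.3f, VIF=%.2f)",
                     rec["variable"], rec["abs_corr"], rec["vif"])
        model_traits = [c for c in trait_cols if c in retained]
        if not model_traits:
            raise ValueError("all model traits removed by the VIF screen")

        stage = "phylogenetic signal"
        signal_results = {}
        lam_rows = []
        for name in model_traits:
            r = estimate_lambda(table[name], cov,
                                log_transform=cfg.log_traits)
            signal_results[name] = r
            lam_rows.append({"trait": name, "lambda": r.lambda_hat,
                             "loglik": r.loglik_at_hat,
                             "loglik0": r.loglik_at_zero,
                             "p_value": r.p_value,
                             "flags": ";".join(r.flags)})
        lambda_table = pd.DataFrame(lam_rows)

        stage = "decomposition"
        results, P, S, skipped = decompose_all(
            table, cov, model_traits,
            signal_results=signal_results if cfg.gate_on_signal else None,
            gate_alpha=cfg.gate_alpha)
        for t in skipped:
            log.info("trait %s not decomposed: "
                     "no significant phylogenetic signal", t)
        vc_table = variance_components_table(results)
        decomposed = list(P.columns)
        decomp = pd.concat(
            {f"{t}_P": P[t] for t in decomposed}
            | {f"{t}_S": S[t] for t in decomposed}, axis=1)

        stage = "ordinal regression"

        def usable(frame):
            # a trait fitted at an h² boundary yields a numerically
            # constant component (P at h²=0, S at h²=1), which carries
            # no information and would make the block design singular;
            # leave it out of that block with a note
            keep = [c for c in frame.columns
                    if frame[c].std() > 1e-9 * (1.0 + abs(frame[c].mean()))]
            for c in frame.columns.difference(keep):
                log.info("predictor %s constant in this block; omitted", c)
            return frame[keep]

        fits = {}
        if decomposed:
            fits["S"] = fit_trait_block(usable(S[decomposed]), status,
                                         joint=cfg.joint)
            fits["P"] = fit_trait_block(usable(P[decomposed]), status,
                                         joint=cfg.joint)
        fits["raw"] = fit_trait_block(table[model_traits], status,
                                       joint=cfg.joint)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    def block_table(fit):
        if isinstance(fit, dict):
            return pd.concat({k: v.table for k, v in fit.items()})
        return fit.table

    return AnalysisReport(
        lambda_table=lambda_table, variance_components=vc_table,
        blocks={k: block_table(v) for k, v in fits.items()},
        block_fits=fits, decomposition=decomp, dropped=[],
        vif_excluded=vif_excluded,
        provenance={"n_species": int(len(table))})


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig,
                 write: bool = True) -> AnalysisReport:
    """Read inputs, run :func:`analyze`, and write all output tables.

    Stage errors propagate with the stage name prefixed; nothing is
    written unless every stage succeeds.
    """
    stage = "read inputs"
    try:
        tree = read_tree(config.tree)
        table = pd.read_csv(config.traits, index_col=0)
        table.index = table.index.astype(str)

        if config.images:
            stage = "morphometrics"
            imgdir = Path(config.images)
            names = sorted(p.stem for p in imgdir.glob("*.png")
                           if not p.stem.endswith("_mask"))
            images = {n: read_specimen(imgdir, n)[0] for n in names}
            morpho = morphometric_table(
                images, include_wings=config.include_wings)
            table = table.join(morpho, how="inner")

        stage = "align"
        trait_cols = [c for c in config.trait_cols if c in table.columns]
        tree, table, dropped = align_inputs(
            tree, table, status_col=config.status_col,
            trait_cols=trait_cols or None)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    report = analyze(tree, table, config)
    report.dropped = dropped
    report.provenance = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "input_checksums": {p: _checksum(p)
                            for p in (config.tree, config.traits)
                            if p and Path(p).exists()},
        "n_species": int(len(table)),
        "dropped": [list(d) for d in dropped],
    }

    if write:
        out = Path(config.out)
        out.mkdir(parents=True, exist_ok=True)
        report.lambda_table.to_csv(out / "lambda_table.csv", index=False)
        report.variance_components.to_csv(
            out / "variance_components.csv", index=False)
        report.decomposition.to_csv(out / "decomposition.csv")
        for name, tab in report.blocks.items():
            tab.to_csv(out / f"block_{name}.csv")
        payload = dict(report.provenance)
        payload["vif_excluded"] = report.vif_excluded
        payload["p_values_in_range"] = bool(all(
            ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
            for tab in report.blocks.values()))
        (out / "report.json").write_text(json.dumps(payload, indent=1,
                                                    sort_keys=True))
    return report
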