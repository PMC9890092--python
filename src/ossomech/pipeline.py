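"""End-to-end orchestration: models -> sweeps -> summaries -> morphospaces.

The pipeline is idempotent for fixed inputs and seed; every output file is
indexed in a JSON manifest with a content hash. Per-taxon failures are
isolated: remaining taxa complete and the errors are collected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import OssomechError
from .model import LimbModel
from .momentarms import aggregate, elbow_protocol, glenohumeral_protocol, sweep
from .phylo import MODES, PhylogeneticPCA, TimeTree, time_scale_tree
from .summaries import ActionSummaryTable, action_ratios, classify_and_sum

DEFAULT_PPCA_MODES = ("bm-correlation", "uniform-bl", "ordinary")

CSV_HEADER = ("# ossomech v{version}; units: angle=deg, length=m, "
              "moment arms dimensionless (r_raw_m / C_min); "
              "positive actions: protraction, adduction, medial_rotation, flexion\n")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    model_paths: list[str] = field(default_factory=list)
    traits_csv: str | None = None  # skip the model stage, go straight to pPCA
    tree_newick: str | None = None
    ages_csv: str | None = None
    min_bl: float = 1.0
    ppca_modes: tuple[str, ...] = DEFAULT_PPCA_MODES
    protocols: tuple[str, ...] = ("glenohumeral", "elbow")
    out_dir: str = "ossomech_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        for p in cfg.model_paths + [p for p in (cfg.traits_csv, cfg.tree_newick,
                                                cfg.ages_csv) if p]:
            if not Path(p).exists():
                raise OssomechError(f"configured input does not exist: {p}")
        for m in cfg.ppca_modes:
            if m not in MODES:
                raise OssomechError(f"unknown ppca mode {m!r}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(CSV_HEADER.format(version=__version__))
        df.to_csv(fh, index_label=index_label)


def sweep_model(model: LimbModel, protocols=("glenohumeral", "elbow")) -> tuple[list, pd.DataFrame]:
    """All (muscle x joint DOF) sweeps for one taxon under the standard
    protocols; returns the aggregated summaries and the long-format table."""
    grids = {}
    if "glenohumeral" in protocols:
        grids["glenohumeral"] = glenohumeral_protocol(model)
    if "elbow" in protocols:
        grids["elbow"] = elbow_protocol(model)
    summaries = []
    frames = []
    for joint, grid in grids.items():
        j = model.joint(joint)
        for muscle in model.muscles:
            if muscle.spanned_joints and joint not in muscle.spanned_joints:
                continue
            for dof in j.dof_names:
                ms = sweep(model, muscle, joint, dof, grid)
                summaries.append(aggregate(ms))
                long = ms.data.copy()
                long.insert(0, "taxon", model.taxon)
                long.insert(1, "muscle", muscle.name)
                long.insert(3, "joint", joint)
                long.insert(4, "dof", dof)
                frames.append(long)
    return summaries, pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {},
        "outputs": {},
        "errors": [],
    }
    for p in list(config.model_paths) + [p for p in (config.traits_csv,
                                                     config.tree_newick,
                                                     config.ages_csv) if p]:
        manifest["inputs"][str(p)] = _sha256(Path(p))

    def register(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    # ----------------------------------------------------------- model stage
    rows = []
    for path in config.model_paths:
        try:
            model = LimbModel.from_json(path)
            summaries, long = sweep_model(model, config.protocols)
            sweep_path = out / f"sweeps_{model.taxon}.csv"
            _write_csv(long, sweep_path, index_label="row")
            register(sweep_path)
            rows.append(classify_and_sum(summaries, model.taxon))
        except OssomechError as e:
            manifest["errors"].append({"model": str(path), "error": str(e)})

    table = None
    if rows:
        table = ActionSummaryTable.from_rows(rows)
        ratios = action_ratios(table)
        summary_path = out / "action_summaries.csv"
        _write_csv(pd.concat([table.data, ratios], axis=1), summary_path, "taxon")
        register(summary_path)

    # ------------------------------------------------------------ pPCA stage
    traits = None
    if config.traits_csv:
        traits = pd.read_csv(config.traits_csv, index_col=0, comment="#")
    elif table is not None and len(table.data) >= 3:
        traits = table.data

    if traits is not None and config.tree_newick:
        tree = None
        if config.ages_csv:
            ages = pd.read_csv(config.ages_csv, comment="#")
            fads = dict(zip(ages.iloc[:, 0], ages["FAD_Ma"]))
            tree = time_scale_tree(Path(config.tree_newick).read_text(), fads,
                                   min_bl=config.min_bl)
        else:
            tree = TimeTree.from_newick(Path(config.tree_newick))
        subsets = {"combined": list(traits.columns)}
        for joint in ("glenohumeral", "elbow"):
            cols = [c for c in traits.columns if c.startswith(joint + "_")]
            if len(cols) >= 2:
                subsets[joint] = cols
        for subset_name, cols in subsets.items():
            for mode in config.ppca_modes:
                try:
                    res = PhylogeneticPCA(traits[cols], tree=tree, mode=mode).fit()
                except OssomechError as e:
                    manifest["errors"].append(
                        {"ppca": f"{subset_name}/{mode}", "error": str(e)})
                    continue
                stem = f"ppca_{subset_name}_{mode}"
                for what, df in (("scores", res.scores), ("loadings", res.loadings)):
                    p = out / f"{stem}_{what}.csv"
                    _write_csv(df, p, "name")
                    register(p)
                eig = pd.DataFrame({
                    "eigenvalue": res.eigenvalues,
                    "variance_proportion": res.variance_proportions,
                }, index=res.loadings.columns)
                p = out / f"{stem}_eigenvalues.csv"
                _write_csv(eig, p, "component")
                register(p)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
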