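"""Config-driven end-to-end orchestration.

A run reads dentitions (CSV/TPS), computes the pairwise distance
tensors, heterodonty and complexity tables, optionally a genetic
distance table (from a FASTA alignment or a ready-made Newick tree),
the species-pair table with the sliding divergence scan, and a
correlation summary against an ecological trait table.  Outputs are
TSVs plus a JSON manifest (package version, config hash, per-stage
counts); reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import __version__
from .align import GridSpec
from .complexity import complexity_table
from .distances import ALL_MEASURES, pairwise_distances
from .heterodonty import (
    aggregate_and_normalize,
    heterodonty_record,
    needed_pairs,
    phenotypic_distance,
)
from .outlines import read_dentition
from .phylo import dg_table, k2p_matrix, nj_tree, read_fasta
from .scan import build_pair_table, composition_annotation, sliding_scan

__all__ = ["RunConfig", "run_pipeline", "correlation_summary"]

FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Flat, serializable run configuration.

    Defaults follow the standard analysis parameters: 1000 outline
    points, 24 harmonics, 100 angle points, scan window 100 with
    offsets 0 and 200, and the bounded alignment grid.
    """

    dentition_dir: str = ""
    dentition_dialect: str = "csv"
    alignment_fasta: str = ""
    tree_newick: str = ""
    traits_tsv: str = ""
    taxonomy_tsv: str = ""
    out_dir: str = "results"
    n_points: int = 1000
    measures: tuple = ALL_MEASURES
    rot_steps: int = 17
    shift_steps: int = 9
    scale_steps: int = 11
    refine: bool = True
    scan_window: int = 100
    scan_offsets: tuple = (0, 200)
    scan_traits: tuple = ("HMT_norm", "HDG_norm", "Cx_combined", "Cx_four", "DP")
    compute_dp: bool = True
    correlation_method: str = "pearson"
    seed: int = 0

    def grid(self) -> GridSpec:
        return GridSpec(
            rot_steps=self.rot_steps,
            shift_steps=self.shift_steps,
            scale_steps=self.scale_steps,
            refine=self.refine,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat TOML config; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("measures", "scan_offsets", "scan_traits"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def _load_dentitions(config: RunConfig):
    directory = Path(config.dentition_dir)
    suffix = ".csv" if config.dentition_dialect == "csv" else ".tps"
    paths = sorted(directory.glob(f"*{suffix}"))
    if not paths:
        raise FileNotFoundError(f"no {suffix} dentitions under {directory}")
    return [read_dentition(p, config.dentition_dialect) for p in paths]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the output tables."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    counts: dict = {}
    grid = config.grid()

    dentitions = _load_dentitions(config)
    counts["dentitions"] = len(dentitions)
    counts["teeth"] = sum(d.n_teeth() for d in dentitions)

    # --- within-species distances -> heterodonty ---------------------------
    records = {}
    tensor_frames = []
    for dentition in dentitions:
        pairs = needed_pairs(dentition)
        tensor = pairwise_distances(
            list(dentition.teeth()),
            measures=config.measures,
            grid=grid,
            pairs=pairs,
            n_points=config.n_points,
        )
        records[dentition.species] = heterodonty_record(
            dentition, tensor, config.measures
        )
        tensor_frames.append(tensor.to_frame())
    counts["within_species_pairs"] = int(sum(len(f) for f in tensor_frames))
    distances_frame = pd.concat(tensor_frames, ignore_index=True)
    outputs["distances"] = distances_frame
    _write_tsv(distances_frame, out_dir / "distances.tsv", index=False)

    measure_table = aggregate_and_normalize(records, config.measures)

    # --- complexity --------------------------------------------------------
    cx = complexity_table(dentitions, n_points=config.n_points)
    outputs["complexity"] = cx
    _write_tsv(cx, out_dir / "complexity.tsv", index=True)
    measure_table = measure_table.join(
        cx[["Cx_exc", "Cx_ang", "Cx_four", "Cx_combined", "cusp_ratio"]]
    )
    outputs["measures"] = measure_table
    _write_tsv(measure_table, out_dir / "measures.tsv", index=True)

    # --- genetic distances -------------------------------------------------
    dg = None
    if config.tree_newick:
        from skbio import TreeNode

        tree = TreeNode.read(str(config.tree_newick))
        dg = dg_table(tree)
    elif config.alignment_fasta:
        alignment = read_fasta(config.alignment_fasta)
        tree = nj_tree(k2p_matrix(alignment))
        tree.write(str(out_dir / "nj_tree.nwk"))
        dg = dg_table(tree)
    if dg is not None:
        outputs["dg"] = dg
        _write_tsv(dg, out_dir / "dg.tsv", index=False)
        counts["species_pairs"] = len(dg)

    # --- pair table and sliding scan --------------------------------------
    if dg is not None:
        taxonomy = None
        if config.taxonomy_tsv:
            tax_frame = pd.read_csv(config.taxonomy_tsv, sep="\t", index_col="species")
            taxonomy = tax_frame.to_dict(orient="index")
        pair_table = build_pair_table(measure_table, dg, taxonomy)

        if config.compute_dp:
            pair_table = _add_phenotypic_distance(pair_table, dentitions, config, grid)

        outputs["pairs"] = pair_table
        _write_tsv(pair_table, out_dir / "pairs.tsv", index=False)

        scans = []
        for trait in config.scan_traits:
            if trait not in pair_table.columns:
                continue
            for offset in config.scan_offsets:
                span = 2 * config.scan_window + offset
                if len(pair_table) < span:
                    continue
                result = sliding_scan(pair_table, trait, config.scan_window, offset)
                result.insert(0, "offset", offset)
                scans.append(result)
        if scans:
            scan_frame = pd.concat(scans, ignore_index=True)
            outputs["scan"] = scan_frame
            _write_tsv(scan_frame, out_dir / "scan.tsv", index=False)
            counts["windows_tested"] = len(scan_frame)
        if taxonomy is not None and len(pair_table) >= config.scan_window:
            comp = composition_annotation(pair_table, config.scan_window)
            outputs["composition"] = comp
            _write_tsv(comp, out_dir / "composition.tsv", index=False)

    # --- ecological correlations -------------------------------------------
    if config.traits_tsv:
        traits = pd.read_csv(config.traits_tsv, sep="\t", index_col="species")
        corr = correlation_summary(measure_table, traits, config.correlation_method)
        outputs["correlations"] = corr
        _write_tsv(corr, out_dir / "correlations.tsv", index=False)

    manifest = {
        "package": "heterodont",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "counts": counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    return outputs


def _add_phenotypic_distance(pair_table, dentitions, config, grid):
    """Compute cross-species DP for every pair, averaged over measures
    of the aligned-free kind plus aligned ones (all configured)."""
    by_species = {d.species: d for d in dentitions}
    from .heterodonty import relative_position_matching

    dp_values = []
    for _, row in pair_table.iterrows():
        a = by_species[row["species_a"]]
        b = by_species[row["species_b"]]
        pairs = set()
        for jaw in ("upper", "lower"):
            ids_a = [t.tooth_id for t in a.rows.get(jaw, [])]
            ids_b = [t.tooth_id for t in b.rows.get(jaw, [])]
            if not ids_a or not ids_b:
                raise ValueError(f"jaw {jaw!r} missing for DP({a.species},{b.species})")
            for i, k in enumerate(relative_position_matching(len(ids_a), len(ids_b))):
                pairs.add(tuple(sorted((ids_a[i], ids_b[k]))))
            for j, l in enumerate(relative_position_matching(len(ids_b), len(ids_a))):
                pairs.add(tuple(sorted((ids_b[j], ids_a[l]))))
        teeth = list(a.teeth()) + list(b.teeth())
        tensor = pairwise_distances(
            teeth,
            measures=config.measures,
            grid=grid,
            pairs=sorted(pairs),
            n_points=config.n_points,
        )
        per_measure = [
            phenotypic_distance(a, b, tensor, m) for m in config.measures
        ]
        dp_values.append(float(np.mean(per_measure)))
    pair_table = pair_table.copy()
    pair_table["DP"] = dp_values
    return pair_table


def correlation_summary(
    measures: pd.DataFrame, traits: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations between every dental measure and every trait.

    Two-sided p-values, no multiple-testing correction.  Constant
    columns yield NaN entries (correlation undefined).
    """
    if method == "pearson":
        corr_fn = pearsonr
    elif method == "spearman":
        corr_fn = spearmanr
    else:
        raise ValueError(f"unknown method {method!r}")
    shared = measures.index.intersection(traits.index)
    if len(shared) < 3:
        raise ValueError("need at least three shared species")
    m_num = measures.loc[shared].select_dtypes(include=[np.number])
    t_num = traits.loc[shared].select_dtypes(include=[np.number])
    rows = []
    for mcol in m_num.columns:
        for tcol in t_num.columns:
            x = m_num[mcol].to_numpy(dtype=float)
            y = t_num[tcol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = corr_fn(x[ok], y[ok])
            rows.append((mcol, tcol, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["measure", "trait", "r", "p", "n"])
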