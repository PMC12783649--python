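"""Single-config orchestration of the full workflow.

Stages run in order — ingest, feature selection, universal dataset,
structure learning, time-resolved rescoring, signal analysis, optional
state PCA, optional conservation analysis — and each persists its
artifacts in the output directory, so any stage can be re-run from the
artifacts of the previous ones (structure learning is the slow stage; the
rescoring layer must be re-runnable per trajectory without relearning the
graph).  A manifest records parameters, seeds, stage timings and artifact
checksums; rerunning with the same config and inputs reproduces all
artifacts bit-exactly.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as cio
from . import dataset as uds
from . import evolution as evo
from . import features as fsel
from . import network as net
from . import signals as sig
from . import states as sta
from . import timeresolved as trm

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with every config violation listed at once."""


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    output_dir: str
    contacts: list[str] = field(default_factory=list)
    fingerprints: list[str] = field(default_factory=list)
    traces: list[str] = field(default_factory=list)
    n_frames: int | None = None
    transition_overrides: list[int] | None = None
    msa: str | None = None
    msa_labels: str | None = None

    neighbor_min_separation: int = 1
    mi_filter_bits: float = fsel.DEFAULT_MI_THRESHOLD_BITS
    combine_mode: str = "intersection"
    sampling_mode: str = "enriched"
    region_frames: int = uds.DEFAULT_REGION_FRAMES
    n_per_traj: int | None = None
    seed: int = 0
    max_parents: int = net.DEFAULT_MAX_PARENTS
    restarts: int = 2
    window_sizes: list[int] = field(default_factory=lambda: list(trm.DEFAULT_WINDOW_SIZES))
    stride: int = trm.DEFAULT_STRIDE
    peak_threshold_bits: float = sig.DEFAULT_PEAK_THRESHOLD_BITS
    evolution_threshold_bits: float = sig.EVOLUTION_HANDOFF_THRESHOLD_BITS
    max_peaks: int = sig.DEFAULT_MAX_PEAKS
    min_peak_separation: int | None = None
    require_all_trajectories: bool = True
    run_states: bool = False
    n_states: int = 3
    pca_components: int = 2
    run_evolution: bool = False
    evolution_target_class: str | None = None
    evolution_positions: list[int] | None = None

    @property
    def grid(self) -> trm.WindowGrid:
        return trm.WindowGrid(tuple(self.window_sizes), self.stride)

    @property
    def peak_separation(self) -> int:
        if self.min_peak_separation is not None:
            return self.min_peak_separation
        return 2 * max(self.window_sizes)

    @property
    def workdir(self) -> Path:
        return Path(self.output_dir)


_BOUNDS = {
    "neighbor_min_separation": (1, None),
    "mi_filter_bits": (0.0, 1.0),
    "region_frames": (1, None),
    "seed": (0, 2**31 - 1),
    "max_parents": (1, 8),
    "restarts": (0, None),
    "stride": (1, None),
    "peak_threshold_bits": (0.0, None),
    "evolution_threshold_bits": (0.0, None),
    "max_peaks": (1, None),
    "n_states": (1, None),
    "pca_components": (1, None),
}


def validate_config(source) -> PipelineConfig:
    """Normalize a config mapping or YAML file into a :class:`PipelineConfig`.

    Unknown keys are rejected; type and bound violations are reported all
    at once with their key paths; referenced input paths must exist.
    """
    import yaml

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    known = set(PipelineConfig.__dataclass_fields__)
    errors = [f"unknown key {k!r}" for k in raw if k not in known]
    if "output_dir" not in raw:
        errors.append("missing required key 'output_dir'")
    cfg = None
    if not errors:
        try:
            cfg = PipelineConfig(**raw)
        except TypeError as exc:
            errors.append(str(exc))
    if cfg is not None:
        for key, (lo, hi) in _BOUNDS.items():
            val = getattr(cfg, key)
            if val is None:
                continue
            if (lo is not None and val < lo) or (hi is not None and val > hi):
                errors.append(f"{key}={val} outside bounds [{lo}, {hi}]")
        if not cfg.contacts and not cfg.fingerprints:
            errors.append("one of 'contacts' or 'fingerprints' must list input files")
        if cfg.contacts and cfg.fingerprints:
            errors.append("'contacts' and 'fingerprints' are mutually exclusive")
        if cfg.combine_mode not in ("intersection", "union"):
            errors.append(f"combine_mode={cfg.combine_mode!r} not in (intersection, union)")
        if cfg.sampling_mode not in ("enriched", "concatenate"):
            errors.append(f"sampling_mode={cfg.sampling_mode!r} not in (enriched, concatenate)")
        if cfg.sampling_mode == "enriched" and cfg.n_per_traj is not None and cfg.n_per_traj < 1:
            errors.append("n_per_traj must be >= 1")
        try:
            cfg.grid
        except ValueError as exc:
            errors.append(f"window_sizes/stride: {exc}")
        if cfg.run_evolution and not cfg.msa:
            errors.append("run_evolution requires 'msa'")
        for key in ("contacts", "fingerprints", "traces"):
            for p in getattr(cfg, key):
                if not Path(p).exists():
                    errors.append(f"{key}: missing file {p}")
        for key in ("msa", "msa_labels"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                errors.append(f"{key}: missing file {p}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    assert cfg is not None
    return cfg


# ---------------------------------------------------------------------------
# stages — each reads upstream artifacts from the workdir and writes its own


def _fingerprint_paths(cfg: PipelineConfig) -> list[Path]:
    return sorted((cfg.workdir / "fingerprints").glob("*.fpt"))


def stage_ingest(cfg: PipelineConfig) -> list[Path]:
    """Normalize inputs into the fingerprint container format."""
    outdir = cfg.workdir / "fingerprints"
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    if cfg.contacts:
        for i, src in enumerate(cfg.contacts):
            records = cio.read_getcontacts(src)
            n_frames = cfg.n_frames or (max(r.frame for r in records) + 1 if records else 0)
            m = cio.binarize(records, n_frames, trajectory_id=f"traj{i}")
            dst = outdir / f"traj{i:03d}.fpt"
            cio.write_fingerprint(m, dst)
            paths.append(dst)
    else:
        for i, src in enumerate(cfg.fingerprints):
            m = cio.read_fingerprint(src)
            if not m.trajectory_id:
                m.trajectory_id = f"traj{i}"
            dst = outdir / f"traj{i:03d}.fpt"
            cio.write_fingerprint(m, dst)
            paths.append(dst)
    return paths


def stage_select(cfg: PipelineConfig) -> list[str]:
    """Neighbor exclusion + MI filter per trajectory, then combination."""
    frames = []
    kept_sets = []
    for p in _fingerprint_paths(cfg):
        m = cio.read_fingerprint(p)
        before = set(m.contact_labels)
        m2 = fsel.exclude_neighbors(m, cfg.neighbor_min_separation)
        neighbor_dropped = before - set(m2.contact_labels)
        _, report = fsel.mi_filter(m2, cfg.mi_filter_bits)
        df = report.to_frame()
        if neighbor_dropped:
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        {
                            "contact": sorted(neighbor_dropped),
                            "trajectory": m.trajectory_id,
                            "kept": False,
                            "reason": "neighbor",
                            "max_mi_bits": np.nan,
                        }
                    ),
                ],
                ignore_index=True,
            )
        frames.append(df)
        kept_sets.append(set(report.kept))
    combined = fsel.combine_features(kept_sets, cfg.combine_mode)
    pd.concat(frames, ignore_index=True).to_csv(
        cfg.workdir / "selection_report.csv", index=False
    )
    (cfg.workdir / "contact_set.txt").write_text("\n".join(combined) + "\n")
    return combined


def _load_contact_set(cfg: PipelineConfig) -> list[str]:
    return (cfg.workdir / "contact_set.txt").read_text().split()


def _restricted_ensemble(cfg: PipelineConfig) -> list[cio.FingerprintMatrix]:
    combined = _load_contact_set(cfg)
    fill = cfg.combine_mode == "union"
    return [
        cio.read_fingerprint(p).restrict(combined, fill_missing=fill)
        for p in _fingerprint_paths(cfg)
    ]


def stage_dataset(cfg: PipelineConfig) -> uds.UniversalDataset:
    """Build and persist the universal dataset D^U."""
    ensemble = _restricted_ensemble(cfg)
    if cfg.sampling_mode == "concatenate":
        data = uds.concatenate(ensemble)
        transitions: list[int | None] = [None] * len(ensemble)
    else:
        transitions = []
        for i, m in enumerate(ensemble):
            if cfg.transition_overrides and cfg.transition_overrides[i] is not None:
                transitions.append(int(cfg.transition_overrides[i]))
                continue
            if not cfg.traces:
                raise ValueError(
                    "enriched sampling needs transition traces or transition_overrides"
                )
            trace = uds.read_trace(cfg.traces[i], smoothing_window=51)
            t_star = uds.detect_transition(trace)
            if t_star is None:
                raise ValueError(f"no transition detected in trace {cfg.traces[i]}")
            transitions.append(t_star)
        n_per = cfg.n_per_traj or max(1, 15000 // len(ensemble))
        data = uds.enriched_sample(
            ensemble, transitions, n_per, cfg.region_frames, cfg.seed
        )
    pd.DataFrame({"transition_frame": transitions}).to_csv(
        cfg.workdir / "transitions.csv", index=False
    )
    cio.write_fingerprint(
        cio.FingerprintMatrix(data.values, data.contact_labels, "universal"),
        cfg.workdir / "universal_dataset.fpt",
    )
    data.provenance.to_csv(cfg.workdir / "dataset_provenance.csv", index=False)
    return data


def _load_dataset(cfg: PipelineConfig) -> uds.UniversalDataset:
    m = cio.read_fingerprint(cfg.workdir / "universal_dataset.fpt")
    prov = pd.read_csv(cfg.workdir / "dataset_provenance.csv")
    return uds.UniversalDataset(m.values, m.contact_labels, prov)


def stage_learn(cfg: PipelineConfig) -> net.UniversalGraph:
    """Learn the universal graph and its static strengths/degrees."""
    data = _load_dataset(cfg)
    graph = net.learn_structure(
        data, max_parents=cfg.max_parents, restarts=cfg.restarts, seed=cfg.seed
    )
    net.edge_strengths(graph, data)
    graph.write_edges_tsv(cfg.workdir / "graph_edges.tsv")
    degrees = net.weighted_degree(graph)
    pd.DataFrame(
        sorted(degrees.items()), columns=["node", "weighted_degree_bits"]
    ).to_csv(cfg.workdir / "node_degrees.csv", index=False)
    return graph


def _load_graph(cfg: PipelineConfig) -> net.UniversalGraph:
    graph = net.UniversalGraph.from_edges_tsv(cfg.workdir / "graph_edges.tsv")
    # isolated nodes are absent from the edge list; restore from the node table
    nodes = pd.read_csv(cfg.workdir / "node_degrees.csv")["node"].tolist()
    return net.UniversalGraph(
        sorted(set(nodes) | set(graph.nodes)), graph.edges, graph.edge_strength
    )


def stage_rescore(cfg: PipelineConfig) -> dict[str, dict[str, trm.TRACTrace]]:
    """Time-resolved rescoring of every trajectory on the universal graph."""
    graph = _load_graph(cfg)
    outdir = cfg.workdir / "traces"
    outdir.mkdir(exist_ok=True)
    all_traces: dict[str, dict[str, trm.TRACTrace]] = {}
    for m in _restricted_ensemble(cfg):
        traces = trm.trac_traces(m, graph, cfg.grid)
        all_traces[m.trajectory_id] = traces
        frames = [t.to_frame() for t in traces.values()]
        frames = [f for f in frames if not f.empty]
        long = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["node", "neighbor", "t", "window", "mi_bits"])
        )
        long.to_csv(outdir / f"{m.trajectory_id}_edges.csv", index=False)
        trm.traces_summary(traces).to_csv(
            outdir / f"{m.trajectory_id}_summary.csv", index=False
        )
    return all_traces


def stage_signals(
    cfg: PipelineConfig, all_traces: dict[str, dict[str, trm.TRACTrace]]
) -> dict:
    """Ranking, key-TRAC selection, ordering and connectors."""
    ranking = sig.rank_contacts(all_traces, cfg.peak_threshold_bits)
    ranking.amplitudes.to_csv(cfg.workdir / "ranking_amplitudes.csv")
    ranking.overlay.to_csv(cfg.workdir / "ranking_overlay.csv")
    peaksets = {
        node: {
            tid: sig.find_peaks(
                all_traces[tid][node], cfg.peak_threshold_bits, cfg.peak_separation
            )
            for tid in all_traces
        }
        for node in ranking.ranking
    }
    key = sig.select_key_tracs(
        ranking,
        peaksets,
        cfg.peak_threshold_bits,
        cfg.require_all_trajectories,
        cfg.max_peaks,
    )
    (cfg.workdir / "key_tracs.txt").write_text("\n".join(key) + "\n")
    rows = []
    for i, a in enumerate(key):
        for b in key[i + 1 :]:
            try:
                label, report = sig.classify_order(peaksets[a], peaksets[b])
            except ValueError:
                label, report = "not_comparable", {"n_compared": 0}
            rows.append((a, b, label, report.get("n_compared", 0)))
    pd.DataFrame(rows, columns=["node_a", "node_b", "order", "n_compared"]).to_csv(
        cfg.workdir / "ordering.csv", index=False
    )
    connectors: list[str] = []
    if len(key) >= 2:
        graph = _load_graph(cfg)
        connectors = sig.find_connectors(graph, key[0], key[1])
        (cfg.workdir / "connectors.txt").write_text("\n".join(connectors) + "\n")
    return {"ranking": ranking, "key_tracs": key, "connectors": connectors}


def stage_states(cfg: PipelineConfig, subnetwork: list[str]) -> None:
    """PCA + state assignment per trajectory over the selected subnetwork."""
    outdir = cfg.workdir / "states"
    outdir.mkdir(exist_ok=True)
    for m in _restricted_ensemble(cfg):
        sub = m.restrict([c for c in subnetwork if c in m.contact_labels])
        proj = sta.pca_project(sub, cfg.pca_components)
        labels = sta.assign_states(proj, cfg.n_states, cfg.seed)
        df = pd.DataFrame(
            proj.scores, columns=[f"pc{i + 1}" for i in range(cfg.pca_components)]
        )
        df["state"] = labels
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(outdir / f"{m.trajectory_id}_states.csv", index=False)
        pd.DataFrame(
            proj.loadings,
            index=proj.contact_labels,
            columns=[f"pc{i + 1}" for i in range(cfg.pca_components)],
        ).to_csv(outdir / f"{m.trajectory_id}_loadings.csv")


def stage_evolve(cfg: PipelineConfig) -> None:
    """Conservation profile and, when a target class is set, specificity."""
    labels_src = cfg.msa_labels if cfg.msa_labels else None
    msa = evo.read_labeled_fasta(cfg.msa, labels_src)
    profile = evo.conservation_score(msa)
    profile.to_frame().to_csv(cfg.workdir / "conservation.csv", index=False)
    if cfg.evolution_target_class:
        positions = cfg.evolution_positions or list(range(1, msa.n_columns + 1))
        result = evo.classify_positions(msa, positions, cfg.evolution_target_class)
        summary = {
            "target_class": result.target_class,
            "n_conserved": len(result.conserved),
            "n_specific": len(result.specific),
            "conserved_positions": result.conserved,
            "specific_positions": result.specific,
            "specificity_ratio": result.ratio,
        }
        (cfg.workdir / "specificity.json").write_text(json.dumps(summary, indent=2))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute all stages in order and write the run manifest.

    Any stage failure aborts with the stage name; artifacts written so far
    are retained alongside a FAILED marker naming the stage.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    state: dict = {}

    def run(name: str, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(cfg, *args)
            timings[name] = round(time.perf_counter() - t0, 3)
            return out
        except Exception as exc:
            (cfg.workdir / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    marker = cfg.workdir / "FAILED"
    if marker.exists():
        marker.unlink()
    run("ingest", stage_ingest)
    run("select", stage_select)
    run("dataset", stage_dataset)
    run("learn", stage_learn)
    all_traces = run("rescore", stage_rescore)
    signals_out = run("signals", stage_signals, all_traces)
    key = signals_out["key_tracs"]
    if cfg.run_states:
        graph = _load_graph(cfg)
        subnet: set[str] = set()
        for hub in key[:2]:
            subnet.add(hub)
            subnet.update(graph.neighbors(hub))
        run("states", stage_states, sorted(subnet) if subnet else _load_contact_set(cfg))
    if cfg.run_evolution:
        run("evolve", stage_evolve)

    artifacts = sorted(
        p for p in cfg.workdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "stage_timings_s": timings,
        "checksums": {str(p.relative_to(cfg.workdir)): _checksum(p) for p in artifacts},
    }
    (cfg.workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
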