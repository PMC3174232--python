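"""End-to-end orchestration of the consensus, descriptor and energy stages.

Every stage is a pure function over in-memory objects; the CLI layers
file I/O and logging on top.  ``PipelineConfig`` collects all tunable
parameters with the study's defaults: 4 Å centroid tolerance, top-4
clusters per conformation, 5 Å contact cutoff, 65% fingerprint overlap
for merging, 50/200-point sliding windows, and the AChBP-calibrated
C-loop range table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clustering import cluster_poses_centroid, cluster_report, top_k_clusters
from .consensus import (
    ClusterRecord,
    ConsensusSite,
    contact_fingerprint,
    merge_across_conformations,
    site_report,
    site_statistics,
)
from .descriptors import (
    DEFAULT_CLOOP_RANGES,
    RangeTable,
    ca_ca_distance,
    classify_cloop,
    series_summary,
)
from .energy import (
    EnergySeries,
    binding_free_energy,
    convergence_delta,
    cumulative_convergence,
)
from .structure_io import NumberingMap, PoseSet, Trajectory, resolve_label

logger = logging.getLogger("namsite")

__all__ = [
    "PipelineConfig",
    "run_consensus_pipeline",
    "run_descriptor_suite",
    "run_energy_audit",
]


@dataclass
class PipelineConfig:
    """All tunable parameters, defaulting to the study's stated values."""

    centroid_tolerance: float = 4.0
    rmsd_tolerance: float = 2.0
    top_k: int = 4
    contact_cutoff: float = 5.0
    merge_threshold: float = 0.65
    overlap_denominator: str = "min"
    fingerprint_mode: str = "union"
    descriptor_window: int = 50
    energy_window: int = 200
    checkpoint_interval: int = 100
    range_table: RangeTable = field(default_factory=lambda: DEFAULT_CLOOP_RANGES)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("centroid_tolerance", "rmsd_tolerance", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.overlap_denominator not in ("min", "jaccard"):
            raise ValueError("overlap_denominator must be 'min' or 'jaccard'")
        for name in ("descriptor_window", "energy_window", "checkpoint_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_text(self) -> str:
        """Dump scalar parameters as a plain-text key=value config."""
        skip = {"range_table"}
        lines = [f"{k} = {v}" for k, v in asdict(self).items() if k not in skip]
        for label, lo, hi in self.range_table.rows:
            lines.append(f"range:{label} = {lo},{hi}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs: dict = {}
        ranges: list[tuple[str, float, float]] = []
        casts = {
            "centroid_tolerance": float, "rmsd_tolerance": float, "top_k": int,
            "contact_cutoff": float, "merge_threshold": float,
            "overlap_denominator": str, "fingerprint_mode": str,
            "descriptor_window": int, "energy_window": int,
            "checkpoint_interval": int, "seed": int,
        }
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("range:"):
                lo, hi = (float(v) for v in value.split(","))
                ranges.append((key[len("range:"):], lo, hi))
            elif key in casts:
                kwargs[key] = casts[key](value)
            else:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
        if ranges:
            kwargs["range_table"] = RangeTable(ranges)
        return cls(**kwargs)


def run_consensus_pipeline(
    ensemble: Trajectory,
    pose_sets: dict[str, list[PoseSet]],
    config: PipelineConfig | None = None,
) -> tuple[list[ConsensusSite], pd.DataFrame, pd.DataFrame]:
    """Blind-docking post-processing across an ensemble.

    ``pose_sets`` maps each ligand id to one :class:`PoseSet` per
    ensemble frame.  Per (ligand, conformation): leader-cluster the
    poses by centroid, keep the top-k clusters, fingerprint them against
    that conformation's frame; then merge fingerprints across all
    conformations and ligands into consensus sites and annotate site
    statistics.  Returns (sites, site table, cluster table).
    """
    config = config or PipelineConfig()
    if not pose_sets:
        raise ValueError("no pose sets given")
    records: list[ClusterRecord] = []
    all_clusters = []
    total_dockings = 0
    n_pairs = 0
    for ligand_id, per_conf in pose_sets.items():
        if len(per_conf) != len(ensemble):
            raise ValueError(
                f"ligand {ligand_id!r}: {len(per_conf)} pose sets for "
                f"{len(ensemble)} ensemble frames"
            )
        for conf_idx, pose_set in enumerate(per_conf):
            n_pairs += 1
            total_dockings += len(pose_set)
            try:
                clusters = cluster_poses_centroid(pose_set, config.centroid_tolerance)
                top = top_k_clusters(clusters, config.top_k)
                for cluster in top:
                    fp = contact_fingerprint(
                        cluster,
                        ensemble[conf_idx],
                        cutoff=config.contact_cutoff,
                        mode=config.fingerprint_mode,
                    )
                    records.append(ClusterRecord(ligand_id, cluster, fp))
                all_clusters.extend(clusters)
            except (ValueError, LookupError) as exc:
                raise RuntimeError(
                    f"consensus stage failed for ligand {ligand_id!r}, "
                    f"conformation {conf_idx}: {exc}"
                ) from exc
    logger.info(
        "consensus: %d ligand-conformation pairs, %d dockings, %d top clusters; "
        "tolerance=%.2f top_k=%d cutoff=%.2f threshold=%.2f denominator=%s",
        n_pairs, total_dockings, len(records), config.centroid_tolerance,
        config.top_k, config.contact_cutoff, config.merge_threshold,
        config.overlap_denominator,
    )
    sites = merge_across_conformations(
        records, threshold=config.merge_threshold,
        denominator=config.overlap_denominator,
    )
    sites = site_statistics(sites, total_dockings, n_pairs)
    return sites, site_report(sites), cluster_report(all_clusters)


def run_descriptor_suite(
    trajectory: Trajectory,
    numbering_map: NumberingMap,
    anchor_pairs: list[tuple[str, str, str, str]],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """C-loop closure series and classification for labelled anchor pairs.

    Each anchor pair is ``(label_a, chain_a, label_b, chain_b)`` in
    canonical numbering (e.g. ``("alpha:C191", "A", "beta:58", "B")``).
    Returns a per-frame table (distance + per-frame state) and a summary
    table ("mean (sd)", state of the mean distance).
    """
    config = config or PipelineConfig()
    per_frame_rows = []
    summary_rows = []
    for label_a, chain_a, label_b, chain_b in anchor_pairs:
        key_a = resolve_label(numbering_map, label_a, chain_a)
        key_b = resolve_label(numbering_map, label_b, chain_b)
        pair_name = f"{label_a}@{chain_a}-{label_b}@{chain_b}"
        distances = np.empty(len(trajectory))
        for i, frame in enumerate(trajectory.frames):
            try:
                distances[i] = ca_ca_distance(frame, key_a, key_b)
            except LookupError as exc:
                raise LookupError(f"frame {i}: {exc}") from exc
            per_frame_rows.append(
                {
                    "pair": pair_name,
                    "frame": i,
                    "distance": distances[i],
                    "state": classify_cloop(distances[i], config.range_table),
                }
            )
        summary = series_summary(distances, with_min=True)
        summary_rows.append(
            {
                "pair": pair_name,
                "mean_sd": str(series_summary(distances)),
                "mean": summary.mean,
                "sd": summary.sd,
                "min": summary.minimum,
                "state_of_mean": classify_cloop(summary.mean, config.range_table),
            }
        )
    return pd.DataFrame(per_frame_rows), pd.DataFrame(summary_rows)


def run_energy_audit(
    energy_tables: dict[str, dict[str, EnergySeries]],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free-energy aggregation and convergence report per complex.

    ``energy_tables`` maps each complex id to its component series
    (keys ``enthalpy`` and ``entropy_TdS``).  Returns a summary table
    (ΔH, TΔS, ΔG with window-mean SDs) and a convergence table of
    cumulative ΔG means at each checkpoint with successive deltas.
    """
    config = config or PipelineConfig()
    summary_rows = []
    convergence_rows = []
    for complex_id, components in energy_tables.items():
        try:
            dH = components["enthalpy"]
            TdS = components["entropy_TdS"]
        except KeyError as exc:
            raise ValueError(f"{complex_id}: missing component {exc}") from exc
        result = binding_free_energy(dH, TdS, window=min(config.energy_window, len(dH)))
        summary_rows.append(
            {
                "complex": complex_id,
                "dH": result.dH_mean, "dH_sd": result.dH_sd,
                "TdS": result.TdS_mean, "TdS_sd": result.TdS_sd,
                "dG": result.dG, "dG_sd": result.dG_sd,
                "n_frames": result.n_frames, "window": result.window,
            }
        )
        TdS_vals = TdS.values
        if len(TdS_vals) == 1:
            TdS_vals = np.full(len(dH), TdS_vals[0])
        dG_series = EnergySeries(dH.values - TdS_vals, label="free_energy")
        checkpoints = cumulative_convergence(dG_series, config.checkpoint_interval)
        prev_mean = None
        for n, mean in checkpoints:
            convergence_rows.append(
                {
                    "complex": complex_id,
                    "n": n,
                    "cumulative_mean": mean,
                    "delta": np.nan if prev_mean is None else abs(mean - prev_mean),
                }
            )
            prev_mean = mean
        if len(dG_series) >= 1500:
            delta = convergence_delta(dG_series, 1400, 1500)
            logger.info("%s: ΔG cumulative-mean change 1400→1500 frames: %.3f kcal/mol",
                        complex_id, delta)
    return pd.DataFrame(summary_rows), pd.DataFrame(convergence_rows)
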