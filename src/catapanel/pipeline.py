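"""Full analysis pipeline: validate -> panelist screening -> panel tests ->
replicate distances + Sammon -> frequency tables -> CA -> consensus
clustering -> cluster profiles, with a manifest-checked report bundle.

Every artifact is a plain CSV/JSON/SVG file; numeric CSVs use a fixed float
format so re-running with the same configuration and seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .dataset import CitationDataset, frequency_table, read_citations, validate_protocol
from .embedding import sammon_map
from .panel import effect_table, per_product_indices, replicate_profile_distances
from .panelist import reproducibility_indices, screen_panelists, summarize_indices
from .products import (
    DISTANCES,
    METHODS,
    VALIDITY_INDICES,
    ca_cell_contributions,
    cluster_products,
    cluster_profile,
    consensus_cluster_count,
    correspondence_analysis,
    select_ca_attributes,
    top_descriptors,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("catapanel")

_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything the full pipeline needs, loadable from YAML/JSON."""

    input_path: str
    output_dir: str
    dialect: str = "long"
    min_citations: int = 2
    max_citations: int = 5
    alpha: float = 0.05
    max_removals: int = 2
    simultaneous_removal: bool = False
    top_n: int = 3
    include_attributes: Sequence[str] = field(default_factory=list)
    exclude_attributes: Sequence[str] = field(default_factory=list)
    n_dims: int = 3
    kmin: int = 2
    kmax: int = 10
    distances: Sequence[str] = field(default_factory=lambda: list(DISTANCES))
    methods: Sequence[str] = field(default_factory=lambda: list(METHODS))
    validity_indices: Sequence[str] = field(default_factory=lambda: list(VALIDITY_INDICES))
    cluster_method: str = "ward.D2"
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class ReportBundle:
    """Paths of every artifact produced by one pipeline run."""

    output_dir: Path
    artifacts: tuple  # relative paths
    manifest: Path
    chosen_k: int
    retained_panelists: tuple
    excluded_panelists: tuple

    def checksums(self) -> dict:
        out = {}
        for rel in self.artifacts:
            out[rel] = _sha256(self.output_dir / rel)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, float_format=_FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig, dataset: Optional[CitationDataset] = None) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    ``dataset`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.input_path``.  Panelists excluded by
    screening are removed from every downstream stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        _write_csv(frame, out / name)
        artifacts.append(name)

    if dataset is None:
        log.info("reading %s (%s dialect)", config.input_path, config.dialect)
        dataset = read_citations(config.input_path, dialect=config.dialect)
    log.info(
        "dataset: %d panelists x %d products x %d replicates x %d attributes",
        dataset.n_panelists, dataset.n_products, dataset.n_replicates, dataset.n_attributes,
    )

    # 1. protocol validation (advisory)
    report = validate_protocol(dataset, config.min_citations, config.max_citations)
    (out / "validation.json").write_text(
        json.dumps(
            {"is_valid": report.is_valid, "violations": [list(v) for v in report.violations]},
            indent=2,
        )
    )
    artifacts.append("validation.json")
    log.info("protocol validation: %d violation(s)", len(report.violations))

    # 2. per-panelist indices, summary, screening
    indices = reproducibility_indices(dataset)
    emit(indices, "panelist_indices.csv")
    summary = summarize_indices(indices)
    emit(
        pd.concat([summary["describe"], summary["correlations"], summary["normality"]],
                  keys=["describe", "correlations", "normality"]),
        "index_summary.csv",
    )
    screening = screen_panelists(
        indices,
        alpha=config.alpha,
        max_removals=config.max_removals,
        simultaneous=config.simultaneous_removal,
    )
    (out / "exclusion_report.json").write_text(json.dumps(screening.to_dict(), indent=2))
    artifacts.append("exclusion_report.json")
    log.info(
        "screening: excluded %d panelist(s) %s; %d retained",
        len(screening.excluded), list(screening.excluded), len(screening.retained),
    )
    retained = dataset.subset_panelists(list(screening.retained))

    # 3. panel-level tests on the retained panel
    effects = effect_table(retained)
    emit(effects, "effect_table.csv")

    ppi = per_product_indices(retained)
    per_product = ppi.table.copy()
    friedman_row = pd.DataFrame(
        {name: [res.p_value] for name, res in ppi.friedman.items()}, index=["friedman_p"]
    )
    emit(pd.concat([per_product, friedman_row]), "per_product_indices.csv")

    # 4. replicate distances + Sammon embedding
    distances = replicate_profile_distances(retained)
    embedding = sammon_map(distances.to_numpy(), dim=2, seed=config.seed)
    coords = pd.DataFrame(
        embedding.coordinates,
        index=["{}:{}".format(*t) for t in distances.index],
        columns=["dim1", "dim2"],
    )
    coords.index.name = "profile"
    emit(coords, "sammon_coordinates.csv")
    log.info("Sammon stress: %.6g after %d iterations", embedding.stress, embedding.n_iter)

    # 5. frequency tables and descriptor ranking
    freq = frequency_table(retained, mode="averaged")
    emit(freq.counts, "frequency_averaged.csv")
    tops = top_descriptors(freq, k=6)
    top_frame = pd.DataFrame(
        {
            product: [f"{a} ({100 * v:.0f}%)" for a, v in entries]
            + [""] * (6 - len(entries))
            for product, entries in tops.items()
        }
    ).T
    top_frame.columns = [f"Descriptor {i + 1}" for i in range(top_frame.shape[1])]
    top_frame.index.name = "product"
    emit(top_frame, "top_descriptors.csv")

    # 6. correspondence analysis on the selected attribute subset
    selected = select_ca_attributes(
        freq,
        top_n=config.top_n,
        include=list(config.include_attributes),
        exclude=list(config.exclude_attributes),
    )
    log.info("CA attribute subset (%d): %s", len(selected), selected)
    ca = correspondence_analysis(freq.counts[selected])
    emit(ca.row_frame(), "ca_row_coordinates.csv")
    emit(ca.col_frame(), "ca_col_coordinates.csv")
    emit(ca_cell_contributions(ca), "ca_contributions.csv")
    inertia = pd.DataFrame(
        {
            "eigenvalue": ca.eigenvalues,
            "explained_pct": ca.explained_inertia,
            "cumulative_pct": np.cumsum(ca.explained_inertia),
        },
        index=[f"Dim{i + 1}" for i in range(ca.n_dimensions)],
    )
    emit(inertia, "ca_inertia.csv")
    log.info("CA: chi2 p=%.4g, dims 1-2 explain %.1f%%",
             ca.chi2_p, ca.explained_inertia[:2].sum())

    # 7. consensus clustering on the first n_dims CA dimensions
    n_dims = min(config.n_dims, ca.n_dimensions)
    points = ca.row_coordinates[:, :n_dims]
    kmax = min(config.kmax, len(points) - 1)
    vote = consensus_cluster_count(
        points,
        kmin=config.kmin,
        kmax=kmax,
        distances=list(config.distances),
        methods=list(config.methods),
        indices=list(config.validity_indices),
        seed=config.seed,
    )
    emit(vote.votes.set_index(["distance", "method", "index"]), "cluster_votes.csv")
    log.info("consensus cluster count: k=%d (tally %s)", vote.chosen_k, vote.tally)
    labels = cluster_products(points, vote.chosen_k, method=config.cluster_method,
                              seed=config.seed)
    members = pd.DataFrame(
        {"cluster": labels}, index=pd.Index(ca.row_labels, name="product")
    )
    emit(members, "cluster_members.csv")

    # 8. cluster profiles and spider data
    profile = cluster_profile(freq, _align_labels(freq, ca.row_labels, labels),
                              attributes=selected)
    emit(profile.counts, "cluster_counts.csv")
    emit(profile.residuals, "cluster_residuals.csv")
    emit(profile.proportions[selected], "spider_data.csv")

    # 9. plots
    if config.make_plots:
        from .plotting import plot_ca_symmetric, plot_sammon, plot_spider

        plot_sammon(embedding, list(distances.index), out / "sammon.svg")
        artifacts.append("sammon.svg")
        plot_ca_symmetric(ca, out / "ca_symmetric.svg")
        artifacts.append("ca_symmetric.svg")
        plot_spider(profile.proportions[selected], out / "spider.svg")
        artifacts.append("spider.svg")

    run_log = {
        "version": _version,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, (tuple,)) else v)
                   for k, v in asdict(config).items()},
        "retained_panelists": list(screening.retained),
        "excluded_panelists": list(screening.excluded),
        "chosen_k": int(vote.chosen_k),
        "ca_chi2_p": ca.chi2_p,
        "sammon_stress": embedding.stress,
    }
    (out / "run.json").write_text(json.dumps(run_log, indent=2, default=str))
    artifacts.append("run.json")

    manifest = out / "MANIFEST.txt"
    lines = [f"{_sha256(out / rel)}  {rel}" for rel in artifacts]
    manifest.write_text("\n".join(lines) + "\n")

    return ReportBundle(
        out, tuple(artifacts), manifest, int(vote.chosen_k),
        tuple(screening.retained), tuple(screening.excluded),
    )


def _align_labels(freq, ca_row_labels, labels) -> np.ndarray:
    """Map cluster labels (ordered like the CA rows) onto the frequency-table rows."""
    by_product = dict(zip(ca_row_labels, labels))
    products = list(freq.counts.index)
    missing = [p for p in products if p not in by_product]
    if missing:
        raise ValueError(f"products missing cluster labels: {missing}")
    return np.asarray([by_product[p] for p in products])
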