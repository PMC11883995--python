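"""Table readers/writers, run configuration, and the end-to-end pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossval as CV
from . import network as NET
from .preprocess import OtuTable, TransformSpec, fit_transform

logger = logging.getLogger(__name__)


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_otu_table(path, orientation: str = "samples_in_rows",
                   sep: str | None = None) -> OtuTable:
    """Read a CSV/TSV count table (first column IDs, header row IDs).

    ``taxa_in_rows`` inputs are transposed so samples are always rows.  The
    delimiter is sniffed from the extension unless given.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0)
    if orientation == "taxa_in_rows":
        df = df.T
    if df.isna().any().any():
        raise ValueError("table contains missing entries")
    counts = df.to_numpy(dtype=float)
    if np.any(counts < 0):
        bad = [(str(df.index[i]), str(df.columns[j]))
               for i, j in np.argwhere(counts < 0)[:10]]
        raise ValueError(f"negative entries at {bad}")
    return OtuTable(
        counts=counts,
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
    )


def write_otu_table(table: OtuTable, path, sep: str | None = None) -> None:
    path = Path(path)
    pd.DataFrame(table.counts, index=table.sample_ids,
                 columns=table.taxon_ids).to_csv(path, sep=_sniff_sep(path, sep))


def summarize_table(table: OtuTable) -> tuple[int, int, float]:
    """(N, D, sparsity %): sparsity is the percentage of zero entries, 2 dp."""
    n, d = table.counts.shape
    sparsity = round(100.0 * float((table.counts == 0).sum()) / (n * d), 2)
    return n, d, sparsity


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    transform: str = "yeojohnson_scale"  # or "scale_only"
    leakage_mode: str = "global"  # or "per_fold"
    outer_k: int = 3
    inner_k: int = 3
    seed: int = 0
    algorithms: tuple[str, ...] = CV.ALL_ALGORITHMS
    n_thresholds: int = 21
    n_lasso_ratios: int = 100
    n_glasso_ratios: int = 20
    sign_convention: str = "partial_correlation"
    output_dir: str = "cooccur_output"

    def __post_init__(self) -> None:
        if self.outer_k < 2:
            raise ValueError("outer_k must be >= 2")
        if not self.algorithms:
            raise ValueError("algorithms must be non-empty")
        for alg in self.algorithms:
            if alg not in CV.ALL_ALGORITHMS:
                raise ValueError(f"unknown algorithm {alg!r}")
        if self.transform not in ("scale_only", "yeojohnson_scale"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.leakage_mode not in ("global", "per_fold"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")

    def cv_config(self) -> CV.CvConfig:
        return CV.CvConfig(
            inner_k=self.inner_k,
            threshold_grid=CV.default_threshold_grid(self.n_thresholds),
            lasso_ratios=CV.default_lasso_ratios(self.n_lasso_ratios),
            glasso_ratios=CV.default_glasso_ratios(self.n_glasso_ratios),
            leakage_mode=self.leakage_mode,
            transform=TransformSpec(method=self.transform),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "algorithms" in doc:
            doc["algorithms"] = tuple(doc["algorithms"])
        return cls(**doc)


def run_pipeline(config: RunConfig, table: OtuTable):
    """Preprocess, evaluate, infer per-fold networks, aggregate, and export.

    Writes tidy CV records, a per-algorithm summary, edge lists, adjacency
    matrices, GraphML files, and a JSON run manifest under
    ``config.output_dir``.  Returns (CvResult, {algorithm: NetworkGraph}).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cv_cfg = config.cv_config()

    logger.info("preprocessing %dx%d table (%s, %s leakage)",
                table.n_samples, table.n_taxa, config.transform, config.leakage_mode)
    if config.leakage_mode == "global":
        data = fit_transform(table.counts, TransformSpec(method=config.transform)).values
    else:
        data = table.counts  # transforms are fit inside each training fold

    logger.info("running %d-fold cross-validation for %s",
                config.outer_k, ", ".join(config.algorithms))
    result = CV.evaluate(data, config.algorithms, k=config.outer_k,
                         seed=config.seed, config=cv_cfg)
    result.records.to_csv(out / "cv_records.csv", index=False)
    result.summary.to_csv(out / "cv_summary.csv")

    graphs: dict[str, NET.NetworkGraph] = {}
    for alg in config.algorithms:
        logger.info("inferring %s network", alg)
        graph, fold_mats = NET.infer_network(
            data, alg, taxon_ids=table.taxon_ids, k=config.outer_k,
            seed=config.seed, config=cv_cfg, sign_convention=config.sign_convention,
        )
        graphs[alg] = graph
        NET.write_edge_list(graph, out / f"edges_{alg}.tsv")
        med = np.median(np.stack([m.weights for m in fold_mats]), axis=0)
        NET.write_adjacency(
            NET.AssociationMatrix(weights=med, taxon_ids=table.taxon_ids, source=alg),
            out / f"adjacency_{alg}.csv",
        )
        NET.write_graphml(graph, out / f"network_{alg}.graphml")

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "versions": _versions(),
        "edge_counts": {alg: g.n_edges for alg, g in graphs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return result, graphs


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn
    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }
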