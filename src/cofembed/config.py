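"""Run configuration shared across pipeline stages.

One validated object carries every tunable with the framework defaults:
five expression levels, 50 embedding dimensions, 100 + 100 negatives,
weight-decay interval 50, 5% held-out edges, softmax temperature 0.5,
d = 20 SVD components and k = 20 mutual neighbors for inferred edges,
top-50 cells in the max score, 200-NN candidate genes and the 1000/5000
rank cutoffs for target-gene calling. A RunConfig serializes into every
output directory so any run can be reproduced from its artifacts plus the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

SCENARIOS = ("rna", "atac", "multiome", "batch", "integration")


@dataclass
class RunConfig:
    scenario: str = "rna"
    seed: int = 0
    # preprocessing
    min_cells: int = 3
    n_levels: int = 5
    n_top_genes: int = 2000
    kmer_length: int = 6
    # embedding
    dim: int = 50
    n_epochs: int = 10
    learning_rate: float = 0.1
    n_neg_uniform: int = 100
    n_neg_degree: int = 100
    wd: float | None = None
    wd_interval: int = 50
    eval_fraction: float = 0.05
    batch_size: int = 1024
    # inferred edges
    svd_components: int = 20
    mnn_neighbors: int = 20
    # transformation and metrics
    temperature: float = 0.5
    metrics_temperature: float = 1.0
    top_k_cells: int = 50
    # regulation
    query_neighbors: int = 200
    peak_rank_cutoff: int = 1000
    avg_rank_cutoff: int = 5000
    # io
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.temperature <= 0 or self.metrics_temperature <= 0:
            raise ValueError("temperatures must be > 0")
        if not (0 <= self.eval_fraction < 1):
            raise ValueError("eval_fraction must be in [0, 1)")

    def embedding_config(self):
        from .embedding import EmbeddingConfig

        return EmbeddingConfig(
            dim=self.dim,
            n_epochs=self.n_epochs,
            learning_rate=self.learning_rate,
            n_neg_uniform=self.n_neg_uniform,
            n_neg_degree=self.n_neg_degree,
            wd=self.wd,
            wd_interval=self.wd_interval,
            eval_fraction=self.eval_fraction,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)
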