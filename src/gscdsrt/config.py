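"""Run configuration: one serialisable object that every pipeline stage
reads its parameters from, with a stable hash stamped into every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    When ``plates_path`` / ``expression_path`` are unset the synthetic
    generator produces the corresponding inputs with the design fields
    below. Group assignment for synthetic cohorts follows the generator's
    MR*/REF* ids; for user data supply ``groups_path`` (2-column TSV:
    culture, group).
    """

    outdir: str = "results"
    seed: int = 0

    # inputs (optional; synthetic when absent)
    plates_path: str | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    drug_class_path: str | None = None

    # synthetic screen design
    n_multiregional: int = 7
    n_reference: int = 14
    n_drugs: int = 115
    doses_per_drug: int = 5
    dose_min: float = 0.4
    dose_max: float = 250.0
    noise_cv: float = 0.05
    intra_sd: float = 2.0
    inter_sd: float = 4.0

    # synthetic expression
    run_expression: bool = True
    n_genes: int = 5000
    n_samples: int = 7

    # scoring
    scaling_mode: str = "dsrt"
    dss_variant: str = "dss2"
    dss_threshold: float = 10.0

    # analysis
    responder_threshold: float = 10.0
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    mixture_threshold: float = 0.998
    cluster_metric: str = "euclidean"
    cluster_method: str = "complete"
    pca_pseudo: float = 0.01

    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters only: where outputs are written
        and how verbosely must not change what they contain."""
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("outdir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
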