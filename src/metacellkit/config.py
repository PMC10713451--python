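"""Run configuration with the toolkit's standard defaults.

The defaults encode the method's published operating point: 50-neighbor
graphs, one metacell per 75 cells, a 0.05 trivial-weight threshold, the
147-base nucleosome-free fragment bound, the 500-base peak width and
5,000x effective-genome-length multiplier of the Poisson open-peak test,
the +/-100 kb peak-gene window with 100 matched background peaks, and
5,000 permutations for differential abundance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import hashlib
import json


@dataclass
class RunConfig:
    seed: int = 0
    modality: str = "rna"
    # manifold
    n_hvg: int = 2500
    n_components_rna: int = 50
    n_components_atac: int = 30
    k: int = 50
    l: int = 15
    n_dcs: int = 10
    kernel_support: str = "union"
    # archetypes
    cells_per_metacell: int = 75
    n_metacells: int | None = None
    trivial_threshold: float = 0.05
    max_iter: int = 150
    tol: float = 1e-5
    maxmin_proportion: float = 1.0
    # atac toolkit
    nfr_bound: int = 147
    peak_width: int = 500
    eff_length_multiplier: int = 5000
    open_p_threshold: float = 0.01
    window_kb: int = 100
    n_background: int = 100
    n_background_bins: int = 100
    link_p_threshold: float = 0.1
    # regulatory
    lasso_folds: int = 10
    # cohort
    meta2_ratio: int = 10
    n_permutations: int = 5000
    da_alpha: float = 0.1
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
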