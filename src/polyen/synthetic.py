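"""Synthetic multi-donor single-cell cohorts with controllable age signal.

The generator emulates the structural assumptions behind polynomial aging
clocks: for a signal gene g, the cell-level (log-scale) expression mean
follows a first- or second-degree polynomial in donor age,

    mu_g(a) = b0 + b1 * a + b2 * a^2,

and the cell-to-cell standard deviation follows a linear trend

    sigma_g(a) = c0 + c1 * a,

capturing the observation that gene expression grows more variable with age.
Non-signal genes have age-constant mean and SD. Cells are drawn independently
per donor; a small per-donor random effect on each gene's mean adds realistic
between-donor variability beyond the age trend.

Two noise laws are available: Gaussian on the log-normalized scale (default;
feeds the pipeline directly) and negative-binomial raw counts with optional
dropout (exercises the size-factor log-normalization path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellExpressionDataset

__all__ = [
    "GeneSignal",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "preset_scenarios",
]


@dataclass(frozen=True)
class GeneSignal:
    """Polynomial coefficients of one signal gene's age trends."""

    gene: int  # index into the gene panel
    b0: float = 3.0
    b1: float = 0.0
    b2: float = 0.0
    c0: float = 0.5
    c1: float = 0.0

    def mean_at(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.b0 + self.b1 * age + self.b2 * age**2

    def sd_at(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.c0 + self.c1 * age


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``signal`` maps cell-type name -> list of :class:`GeneSignal`; genes not
    listed are age-independent with baseline mean drawn uniformly from
    ``baseline_mean_range`` and SD ``baseline_sd``. ``low_cell_donors`` gives
    the first k donors only ``low_cell_count`` cells of each type, to exercise
    the minimum-cell filter downstream.
    """

    n_donors: int = 40
    age_range: tuple[float, float] = (20.0, 80.0)
    n_genes: int = 50
    cell_types: dict[str, int] = field(default_factory=lambda: {"TypeA": 200})
    signal: dict[str, list[GeneSignal]] = field(default_factory=dict)
    baseline_mean_range: tuple[float, float] = (1.0, 3.0)
    baseline_sd: float = 0.5
    donor_effect_sd: float = 0.05
    noise: str = "lognormal"  # or "nb_counts"
    nb_dispersion: float = 5.0
    dropout_rate: float = 0.0
    low_cell_donors: int = 0
    low_cell_count: int = 1
    scenario: str = "custom"
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        """Write the spec as a YAML scenario config."""
        import dataclasses

        import yaml

        payload = dataclasses.asdict(self)
        payload["age_range"] = list(self.age_range)
        payload["baseline_mean_range"] = list(self.baseline_mean_range)
        payload["signal"] = {
            ct: [dataclasses.asdict(s) for s in sigs] for ct, sigs in self.signal.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["age_range"] = tuple(payload.get("age_range", (20.0, 80.0)))
        payload["baseline_mean_range"] = tuple(
            payload.get("baseline_mean_range", (1.0, 3.0))
        )
        payload["signal"] = {
            ct: [GeneSignal(**s) for s in sigs]
            for ct, sigs in (payload.get("signal") or {}).items()
        }
        return cls(**payload)

    def __post_init__(self) -> None:
        if self.noise not in ("lognormal", "nb_counts"):
            raise ValueError(f"unknown noise law {self.noise!r}")
        if not self.cell_types:
            raise ValueError("at least one cell type is required")
        lo, hi = self.age_range
        for ct, sigs in self.signal.items():
            if ct not in self.cell_types:
                raise ValueError(f"signal for unknown cell type {ct!r}")
            for s in sigs:
                if not (0 <= s.gene < self.n_genes):
                    raise ValueError(f"signal gene index {s.gene} outside the panel")
                for a in (lo, hi):
                    if s.sd_at(a) <= 0:
                        raise ValueError(
                            f"sigma_g(a) must stay positive over the age range; "
                            f"gene {s.gene} has sd {s.sd_at(a):.3f} at age {a:g}"
                        )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    signal_genes: dict[str, list[str]]  # cell type -> gene symbols
    coefficients: pd.DataFrame
    scenario: str
    seed: int

    def all_signal_genes(self) -> list[str]:
        return sorted({g for genes in self.signal_genes.values() for g in genes})


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _donor_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"D{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(spec: CohortSpec) -> tuple[CellExpressionDataset, SyntheticTruth]:
    """Draw a cohort deterministically from ``spec.seed``.

    Returns the dataset (log-normalized for the Gaussian noise law, raw counts
    for ``nb_counts``) and the ground truth. Gaussian values are clipped at 0,
    matching the non-negativity of log-normalized expression; baseline means
    are far enough from 0 that clipping is negligible.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    donors = _donor_names(spec.n_donors)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_donors)

    # age-independent baselines, shared across cell types
    base_mean = rng.uniform(*spec.baseline_mean_range, size=spec.n_genes)
    signal_lookup = {
        ct: {s.gene: s for s in sigs} for ct, sigs in spec.signal.items()
    }

    blocks, cell_rows = [], []
    for d_idx, donor in enumerate(donors):
        age = ages[d_idx]
        donor_shift = rng.normal(0.0, spec.donor_effect_sd, size=spec.n_genes)
        for ct, n_cells in spec.cell_types.items():
            if d_idx < spec.low_cell_donors:
                n_cells = spec.low_cell_count
            mu = base_mean + donor_shift
            sd = np.full(spec.n_genes, spec.baseline_sd)
            for g_idx, sig in signal_lookup.get(ct, {}).items():
                mu = mu.copy()
                sd = sd.copy()
                mu[g_idx] = sig.mean_at(age) + donor_shift[g_idx]
                sd[g_idx] = sig.sd_at(age)
            values = rng.normal(mu, sd, size=(n_cells, spec.n_genes))
            if spec.noise == "lognormal":
                block = np.clip(values, 0.0, None)
            else:
                lam = np.clip(np.expm1(np.clip(values, 0.0, None)), 1e-9, None)
                # NB as gamma-Poisson with shape = dispersion
                shape = spec.nb_dispersion
                lam_g = rng.gamma(shape, lam / shape)
                block = rng.poisson(lam_g).astype(float)
                if spec.dropout_rate > 0:
                    block *= rng.random(block.shape) >= spec.dropout_rate
            blocks.append(block)
            cell_rows += [
                {"cell_id": f"{donor}_{ct}_{i:04d}", "donor_id": donor, "cell_type": ct}
                for i in range(n_cells)
            ]

    values = np.vstack(blocks)
    cells = pd.DataFrame(cell_rows)
    group = np.where(np.arange(spec.n_donors) % 2 == 0, "non-smoker", "smoker")
    donors_table = pd.DataFrame(
        {
            "donor_id": donors,
            "age": ages,
            "group": group,
            "study": f"synthetic:{spec.scenario}",
        }
    )
    dataset = CellExpressionDataset(
        values=values,
        cell_annotations=cells,
        donor_annotations=donors_table,
        gene_ids=genes,
        normalized=(spec.noise == "lognormal"),
        name=f"synthetic-{spec.scenario}",
    )

    coeff_rows = [
        {
            "cell_type": ct,
            "gene": genes[s.gene],
            "b0": s.b0,
            "b1": s.b1,
            "b2": s.b2,
            "c0": s.c0,
            "c1": s.c1,
        }
        for ct, sigs in spec.signal.items()
        for s in sigs
    ]
    truth = SyntheticTruth(
        signal_genes={ct: [genes[s.gene] for s in sigs] for ct, sigs in spec.signal.items()},
        coefficients=pd.DataFrame(
            coeff_rows, columns=["cell_type", "gene", "b0", "b1", "b2", "c0", "c1"]
        ),
        scenario=spec.scenario,
        seed=spec.seed,
    )
    return dataset, truth


def preset_scenarios(seed: int = 0) -> dict[str, CohortSpec]:
    """The named study conditions used throughout tests and examples.

    - ``strong_mean``: 5 of 50 genes with linear mean trends — the
      parameter-recovery scenario (40 donors, 200 cells/donor).
    - ``quadratic``: rise-then-fall mean trends (b2 < 0), echoing genes that
      participate in part of the aging process and then decline.
    - ``variance_only``: means flat in age, cell-level SD increasing — only
      variance features carry signal.
    - ``null``: no signal genes at all.
    - ``small_smoker_like``: a small cohort (12 donors) with smoker /
      non-smoker groups, prone to overfitting.
    """
    strong_signals = [
        GeneSignal(gene=0, b0=2.5, b1=0.020, c0=0.5),
        GeneSignal(gene=1, b0=3.8, b1=-0.018, c0=0.5),
        GeneSignal(gene=2, b0=2.2, b1=0.025, c0=0.5),
        GeneSignal(gene=3, b0=2.8, b1=0.015, c0=0.5),
        GeneSignal(gene=4, b0=4.0, b1=-0.022, c0=0.5),
    ]
    quad_signals = [
        GeneSignal(gene=0, b0=0.5, b1=0.100, b2=-0.0010, c0=0.5),
        GeneSignal(gene=1, b0=0.8, b1=0.080, b2=-0.0008, c0=0.5),
        GeneSignal(gene=2, b0=0.4, b1=0.120, b2=-0.0012, c0=0.5),
        GeneSignal(gene=3, b0=0.6, b1=0.090, b2=-0.0009, c0=0.5),
        GeneSignal(gene=4, b0=0.5, b1=0.110, b2=-0.0011, c0=0.5),
    ]
    # baseline mean kept ~4 SD above zero so the non-negativity clip cannot
    # leak an age trend into donor means (the scenario's defining property)
    var_signals = [
        GeneSignal(gene=g, b0=5.0, b1=0.0, c0=0.3, c1=0.012) for g in range(5)
    ]
    small_signals = [
        GeneSignal(gene=0, b0=2.5, b1=0.020, c0=0.5),
        GeneSignal(gene=1, b0=3.5, b1=-0.015, c0=0.5),
        GeneSignal(gene=2, b0=2.0, b1=0.025, c0=0.5),
    ]
    return {
        "strong_mean": CohortSpec(
            signal={"TypeA": strong_signals}, scenario="strong_mean", seed=seed
        ),
        "quadratic": CohortSpec(
            signal={"TypeA": quad_signals}, scenario="quadratic", seed=seed
        ),
        "variance_only": CohortSpec(
            signal={"TypeA": var_signals}, scenario="variance_only", seed=seed
        ),
        "null": CohortSpec(signal={}, scenario="null", seed=seed),
        "small_smoker_like": CohortSpec(
            n_donors=12,
            n_genes=30,
            cell_types={"TypeA": 60},
            signal={"TypeA": small_signals},
            scenario="small_smoker_like",
            seed=seed,
        ),
    }
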