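"""Synthetic study-like datasets with known per-gene ground truth.

The generator emulates the structure of a five-species comparative
expression study: a time-calibrated five-taxon tree (root height 11.8 MY,
youngest split 5.5 MY), 6-12 biological replicates per species split over
two sexes, ~2000 genes on the log2 FPKM scale, heterogeneous per-species
within-gene variances, and genes drawn from a mixture of evolutionary
regimes (conserved, drift, stabilizing selection, and directed tip shifts
up or down).  Every gene records the regime and generating parameters, so
downstream tests can score recovery against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .models import Model, ModelParams, ModelSpec, simulate_gene
from .trees import Phylogeny, parse_newick

__all__ = [
    "GroundTruth",
    "fixture_tree",
    "generate_dataset",
    "write_bundle",
    "DEFAULT_MIXTURE",
    "DEFAULT_REPLICATES",
]

SPECIES = ("charithonia", "sara", "erato", "doris", "melpomene")

# per-sex replicate counts (female, male); totals 12, 11, 6, 12, 8 -> 49
DEFAULT_SEX_REPLICATES = {
    "charithonia": (6, 6),
    "sara": (5, 6),
    "erato": (3, 3),
    "doris": (6, 6),
    "melpomene": (4, 4),
}
DEFAULT_REPLICATES = {sp: f + m
                      for sp, (f, m) in DEFAULT_SEX_REPLICATES.items()}

# regime mixture mirroring the study's headline proportions: ~3% conserved
# or under stabilizing selection, ~81% drifting, ~16% shifted on one tip
DEFAULT_MIXTURE = {
    "conserved": 0.03,
    "drift": 0.81,
    "ou": 0.0,
    "shift_up": 0.08,
    "shift_down": 0.08,
}

REGIMES = ("conserved", "drift", "ou", "shift_up", "shift_down")


def fixture_tree(root_age: float = 11.8,
                 erato_split: float = 8.5,
                 sara_charithonia_split: float = 5.5,
                 doris_melpomene_split: float = 9.0) -> Phylogeny:
    """The five-taxon study tree: erato groups with (sara, charithonia)
    against (doris, melpomene).

    Node ages are in million years and configurable; the defaults place the
    root at 11.8 MY and the youngest split at 5.5 MY, with the remaining
    internal ages chosen inside that range.
    """
    if not (root_age > erato_split > sara_charithonia_split > 0
            and root_age > doris_melpomene_split > 0):
        raise ValueError("node ages must decrease from the root")
    e, sc, dm, r = erato_split, sara_charithonia_split, doris_melpomene_split, \
        root_age
    newick = (
        f"((erato:{e},(sara:{sc},charithonia:{sc}):{e - sc}):{r - e},"
        f"(doris:{dm},melpomene:{dm}):{r - dm}):0;"
    )
    return parse_newick(newick)


@dataclass
class GroundTruth:
    """Per-gene generating regime and parameters for one synthetic dataset."""

    regimes: list[str]
    params: list[ModelParams]
    foregrounds: list[str | None]
    seed: int

    def __post_init__(self) -> None:
        bad = set(self.regimes) - set(REGIMES)
        if bad:
            raise ValueError(f"unknown regimes {bad}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (reg, par, fg) in enumerate(
                zip(self.regimes, self.params, self.foregrounds)):
            rows.append({
                "gene": f"g{i:05d}",
                "regime": reg,
                "foreground": fg or "",
                "params": par.to_json(),
            })
        return pd.DataFrame(rows)


def _draw_params(regime: str, rng: np.random.Generator, species,
                 delta2_meanlog: float, delta2_sdlog: float
                 ) -> tuple[ModelSpec, ModelParams]:
    mu0 = rng.uniform(2.0, 8.0)
    d2 = {sp: float(np.exp(rng.normal(delta2_meanlog, delta2_sdlog)))
          for sp in species}
    if regime == "conserved":
        return ModelSpec(Model.EQUAL_MEANS), \
            ModelParams(mu=mu0, delta2=d2)
    if regime == "drift":
        s2 = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
        return ModelSpec(Model.BM), \
            ModelParams(sigma2=s2, delta2=d2, root=mu0)
    if regime == "ou":
        s2 = float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))
        alpha = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
        return ModelSpec(Model.OU), \
            ModelParams(sigma2=s2, alpha=alpha, theta=mu0, delta2=d2)
    # directed tip shift: an OU_SHIFT gene whose foreground optimum sits a
    # few log2 units above (up) or below (down) the background optimum
    sign = 1.0 if regime == "shift_up" else -1.0
    fg = species[rng.integers(len(species))]
    s2 = float(np.exp(rng.uniform(np.log(0.05), np.log(0.5))))
    delta = rng.uniform(2.0, 5.0)
    params = ModelParams(sigma2_B=s2, sigma2_F=s2, alpha=0.5,
                         theta_B=mu0, theta_F=float(mu0 + sign * delta),
                         delta2=d2)
    return ModelSpec(Model.OU_SHIFT, fg), params


def generate_dataset(tree: Phylogeny, n_genes: int,
                     mixture: dict[str, float] | None = None,
                     replicates: dict[str, int] | None = None,
                     delta2_meanlog: float = float(np.log(0.2)),
                     delta2_sdlog: float = 0.8,
                     seed: int = 0) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate a full genes x samples dataset plus its ground truth.

    Per gene: a regime is drawn from ``mixture``, generating parameters are
    drawn from regime-specific ranges, and replicates are simulated with
    :func:`expevo.models.simulate_gene`.  Per-species within-species
    variances are log-normal, drawn independently per gene and species, so
    variance vectors are uncorrelated across species by construction.
    Fully reproducible from ``seed``.
    """
    mixture = dict(DEFAULT_MIXTURE if mixture is None else mixture)
    unknown = set(mixture) - set(REGIMES)
    if unknown:
        raise ValueError(f"unknown regimes in mixture: {unknown}")
    probs = np.array([mixture.get(r, 0.0) for r in REGIMES], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("mixture proportions must be non-negative and "
                         "sum to 1")
    replicates = dict(DEFAULT_REPLICATES if replicates is None
                      else replicates)
    species = tree.tips
    for sp in species:
        c = replicates.get(sp, 0)
        if not 2 <= c <= 12:
            raise ValueError(f"replicate count for {sp} must be in [2, 12]")

    rng = np.random.default_rng(seed)
    regimes, params_list, fgs = [], [], []
    columns: dict[str, np.ndarray] = {}
    sample_ids = [f"{sp}_r{i + 1}" for sp in species
                  for i in range(replicates[sp])]
    species_of = {sid: sid.rsplit("_r", 1)[0] for sid in sample_ids}
    rows = np.empty((n_genes, len(sample_ids)))
    for g in range(n_genes):
        regime = REGIMES[rng.choice(len(REGIMES), p=probs)]
        spec, params = _draw_params(regime, rng, species,
                                    delta2_meanlog, delta2_sdlog)
        obs = simulate_gene(spec, params, tree, replicates, rng)
        rows[g] = np.concatenate([obs.values[sp] for sp in species])
        regimes.append(regime)
        params_list.append(params)
        fgs.append(spec.foreground)
    matrix = pd.DataFrame(rows, columns=sample_ids,
                          index=[f"g{i:05d}" for i in range(n_genes)])
    dataset = ExpressionDataset(matrix=matrix, species_of=species_of)
    truth = GroundTruth(regimes=regimes, params=params_list,
                        foregrounds=fgs, seed=seed)
    return dataset, truth


def write_bundle(dataset: ExpressionDataset, truth: GroundTruth,
                 outdir) -> dict[str, Path]:
    """Write a ready-to-analyze bundle: FPKM matrix TSV, sample-to-species
    map TSV, and the ground-truth TSV.  Byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression_fpkm.tsv",
        "species_map": outdir / "species_map.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    fpkm = np.power(2.0, dataset.matrix)
    fpkm.to_csv(paths["expression"], sep="\t", index_label="gene")
    with open(paths["species_map"], "w") as fh:
        for sid in dataset.matrix.columns:
            fh.write(f"{sid}\t{dataset.species_of[sid]}\n")
    truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
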