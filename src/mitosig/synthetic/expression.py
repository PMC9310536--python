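"""Negative-binomial single-cell count simulation with a stress subpopulation.

The generator emulates droplet scRNA-Seq of suction-blister epidermis:
cells belong to states (basal/spinous/granular keratinocytes, melanocytes,
immune cells and — only in lesional samples by default — stress
keratinocytes).  Counts are negative binomial with log-normal gene-wise
means and log-normal library sizes.  Stress-state cells carry programmed
log2 fold changes on three gene sets: oxidative phosphorylation up,
glycolysis down, stress markers (stress keratins/alarmins/chemokines) up.
Every effect is known exactly, so signature scoring, the enrichment scan,
DE counting and composition analysis can all be validated against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["ExpressionSimSpec", "synth_expression", "default_pathways"]

KERATINOCYTE_STATES = (
    "basal",
    "spinous",
    "granular",
    "stress",
)

_DEFAULT_CELLS: dict[tuple[str, str], int] = {
    ("nonlesional", "basal"): 500,
    ("nonlesional", "spinous"): 350,
    ("nonlesional", "granular"): 200,
    ("nonlesional", "melanocyte"): 100,
    ("nonlesional", "immune"): 50,
    ("lesional", "basal"): 450,
    ("lesional", "spinous"): 320,
    ("lesional", "granular"): 180,
    ("lesional", "melanocyte"): 30,
    ("lesional", "immune"): 120,
    ("lesional", "stress"): 200,
}

_METABOLIC_PATHWAYS = (
    "oxphos",
    "glycolysis",
    "tca_cycle",
    "fatty_acid_oxidation",
    "fatty_acid_synthesis",
    "pentose_phosphate",
    "glutaminolysis",
    "one_carbon_metabolism",
    "serine_biosynthesis",
    "nucleotide_synthesis",
    "urea_cycle",
    "heme_metabolism",
    "cholesterol_biosynthesis",
    "sphingolipid_metabolism",
    "glycogen_metabolism",
    "branched_chain_aa_catabolism",
    "beta_alanine_metabolism",
    "proline_metabolism",
    "nad_metabolism",
    "glutathione_metabolism",
    "arachidonic_acid_metabolism",
)


def default_pathways(
    n_genes: int, genes_per_set: int = 20, n_stress_markers: int = 30
) -> dict[str, list[str]]:
    """Disjoint demo gene sets: 21 metabolic pathways plus stress markers.

    Genes are named ``G00001..``; the sets tile the start of the gene list
    so they exist in any simulated matrix of at least
    ``21 * genes_per_set + n_stress_markers`` genes.
    """
    needed = len(_METABOLIC_PATHWAYS) * genes_per_set + n_stress_markers
    if n_genes < needed:
        raise ValueError(f"need >= {needed} genes for the default sets")
    names = [f"G{i + 1:05d}" for i in range(n_genes)]
    sets: dict[str, list[str]] = {}
    pos = 0
    for p in _METABOLIC_PATHWAYS:
        sets[p] = names[pos : pos + genes_per_set]
        pos += genes_per_set
    sets["stress_markers"] = names[pos : pos + n_stress_markers]
    return sets


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Specification of one simulated cell x gene count matrix."""

    n_genes: int = 2000
    cells: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_CELLS)
    )
    pathway_assignments: Optional[Mapping[str, Sequence[str]]] = None
    lfc_oxphos: float = 1.0
    lfc_glycolysis: float = -1.0
    lfc_stress: float = 2.0
    dispersion: float = 0.5
    lib_size_mean: float = 5000.0
    lib_size_sigma: float = 0.3  # log-normal sigma of library size
    n_samples_per_condition: int = 3
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.lfc_oxphos < 0:
            raise ValueError("lfc_oxphos must be >= 0")
        if self.lfc_glycolysis > 0:
            raise ValueError("lfc_glycolysis must be <= 0")
        if self.lfc_stress < 0:
            raise ValueError("lfc_stress must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        for (cond, state), n in self.cells.items():
            if n < 0:
                raise ValueError(f"negative cell count for {(cond, state)}")

    def resolve_sets(self) -> dict[str, list[str]]:
        sets = (
            {k: list(v) for k, v in self.pathway_assignments.items()}
            if self.pathway_assignments is not None
            else default_pathways(self.n_genes)
        )
        if not self.allow_overlap:
            seen: dict[str, str] = {}
            for name, genes in sets.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g} appears in both {seen[g]!r} and {name!r}; "
                            "pass allow_overlap=True to permit overlapping sets"
                        )
                    seen[g] = name
        return sets


def synth_expression(spec: ExpressionSimSpec) -> ad.AnnData:
    """Simulate the count matrix; returns an AnnData.

    ``obs`` carries ``sample``, ``condition`` and ``cell_state``;
    ``uns["gene_sets"]`` the resolved gene sets and ``uns["ground_truth"]``
    the programmed log2 fold changes.  Stress-state cells multiply the
    gene-wise means of the oxphos / glycolysis / stress-marker sets by
    ``2**lfc``; every other state uses the baseline means plus small
    state-specific marker shifts placed outside the annotated sets.
    """
    spec.validate()
    sets = spec.resolve_sets()
    rng = np.random.default_rng(spec.seed)

    gene_names = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    for set_name, genes in sets.items():
        missing = [g for g in genes if g not in name_to_idx]
        if missing:
            raise ValueError(f"set {set_name!r} references unknown genes: {missing[:5]}")

    # gene-wise base mean on a relative scale (log-normal, natural log)
    base_mean = rng.lognormal(mean=1.0, sigma=1.0, size=spec.n_genes)

    # state identity markers outside the annotated sets so null pathways
    # stay null: each non-stress state upregulates a private gene block
    annotated = {name_to_idx[g] for genes in sets.values() for g in genes}
    free = [i for i in range(spec.n_genes) if i not in annotated]
    states = sorted({state for (_, state) in spec.cells if state != "stress"})
    marker_blocks: dict[str, np.ndarray] = {}
    block = 20
    for i, state in enumerate(states):
        lo = (i * block) % max(len(free) - block, 1)
        marker_blocks[state] = np.array(free[lo : lo + block], dtype=int)

    def state_means(condition: str, state: str) -> np.ndarray:
        m = base_mean.copy()
        if state in marker_blocks and len(marker_blocks[state]):
            m[marker_blocks[state]] *= 2.0
        if state == "stress":
            for set_name, lfc in (
                ("oxphos", spec.lfc_oxphos),
                ("glycolysis", spec.lfc_glycolysis),
                ("stress_markers", spec.lfc_stress),
            ):
                if set_name in sets:
                    idx = [name_to_idx[g] for g in sets[set_name]]
                    m[idx] *= 2.0**lfc
        return m

    rows = []
    obs_rows = []
    cell_id = 0
    for (condition, state), n_cells in sorted(spec.cells.items()):
        mu_gene = state_means(condition, state)
        mu_gene = mu_gene / mu_gene.sum()
        for j in range(n_cells):
            sample = (
                f"{condition[:3].upper()}{j % spec.n_samples_per_condition + 1}"
            )
            lib = rng.lognormal(
                mean=np.log(spec.lib_size_mean) - spec.lib_size_sigma**2 / 2,
                sigma=spec.lib_size_sigma,
            )
            mu = mu_gene * lib
            if spec.dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / spec.dispersion, scale=mu * spec.dispersion
                )
            else:
                lam = mu
            rows.append(rng.poisson(lam))
            obs_rows.append(
                {
                    "cell_id": f"C{cell_id:06d}",
                    "sample": sample,
                    "condition": condition,
                    "cell_state": state,
                }
            )
            cell_id += 1
    X = np.asarray(rows, dtype=np.int32)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.uns["gene_sets"] = {k: list(v) for k, v in sets.items()}
    adata.uns["ground_truth"] = {
        "lfc_oxphos": spec.lfc_oxphos,
        "lfc_glycolysis": spec.lfc_glycolysis,
        "lfc_stress": spec.lfc_stress,
        "dispersion": spec.dispersion,
    }
    return adata
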