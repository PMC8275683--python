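"""Seeded synthetic cohorts with planted Boolean structure.

The generator plants gene modules that are mutually equivalent within a
module and opposite (or equivalent) across modules depending on their
healthy/disease side, plus non-bimodal noise genes, and emits the ground
truth needed to score every pipeline stage exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleAnnotation
from .stepminer import DEFAULT_MARGIN

__all__ = ["ModuleSpec", "SyntheticSpec", "generate_cohort", "generate_trial_fixture"]

_SIDES = ("healthy_up", "disease_up")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted gene module: size, polarity and effect size (in noise SDs)."""

    size: int
    side: str  # healthy_up | disease_up
    delta: float


@dataclass
class SyntheticSpec:
    n_samples: int = 100
    class_fractions: tuple[float, float] = (0.5, 0.5)  # (healthy, disease)
    modules: list[ModuleSpec] = field(default_factory=list)
    n_noise_genes: int = 20
    noise_sd: float = 1.0
    intermediate_fraction: float = 0.05
    seed: int = 0
    baseline: float = 8.0  # log2-scale pedestal for all genes
    margin: float = DEFAULT_MARGIN

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if len(self.class_fractions) != 2 or abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must be two fractions summing to 1")
        if min(self.class_fractions) <= 0:
            raise ValueError("class_fractions must be positive")
        for k, module in enumerate(self.modules):
            if module.size <= 0:
                raise ValueError(f"modules[{k}].size must be positive")
            if module.side not in _SIDES:
                raise ValueError(f"modules[{k}].side must be one of {_SIDES}")
            if module.delta < 0:
                raise ValueError(f"modules[{k}].delta must be >= 0")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.intermediate_fraction < 1:
            raise ValueError("intermediate_fraction must be in [0, 1)")


def _module_gene_ids(spec: SyntheticSpec) -> dict[str, list[str]]:
    names: dict[str, list[str]] = {}
    for k, module in enumerate(spec.modules):
        mid = f"M{k + 1}"
        names[mid] = [f"{mid}_G{g + 1:03d}" for g in range(module.size)]
    return names


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, dict]:
    """Generate a two-class cohort with planted module structure.

    Module genes are drawn N(baseline +/- delta/2, noise_sd) with the sign
    set by (sample class x module side); noise genes are N(baseline,
    noise_sd) and therefore non-bimodal.  A fraction of module-gene values
    is nudged into the intermediate zone around the planted threshold.
    The truth dict lists module memberships, expected cross-module
    relations, and the planted discriminative path (all healthy-side
    modules followed by all disease-side modules).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_healthy = int(round(spec.class_fractions[0] * spec.n_samples))
    n_healthy = min(max(n_healthy, 2), spec.n_samples - 2)
    labels = ["healthy"] * n_healthy + ["disease"] * (spec.n_samples - n_healthy)
    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    is_healthy = np.array([l == "healthy" for l in labels])

    module_genes = _module_gene_ids(spec)
    gene_ids: list[str] = [g for genes in module_genes.values() for g in genes]
    gene_ids += [f"N_G{g + 1:03d}" for g in range(spec.n_noise_genes)]

    values = np.empty((len(gene_ids), spec.n_samples))
    row = 0
    for module in spec.modules:
        up_in_healthy = module.side == "healthy_up"
        shift = np.where(is_healthy == up_in_healthy, module.delta / 2.0, -module.delta / 2.0)
        shift = shift * spec.noise_sd
        for _ in range(module.size):
            values[row] = spec.baseline + shift + rng.normal(0.0, spec.noise_sd, spec.n_samples)
            if spec.intermediate_fraction > 0:
                k = int(round(spec.intermediate_fraction * spec.n_samples))
                if k:
                    cols = rng.choice(spec.n_samples, size=k, replace=False)
                    values[row, cols] = spec.baseline + rng.uniform(
                        -spec.margin / 2, spec.margin / 2, k
                    )
            row += 1
    for _ in range(spec.n_noise_genes):
        values[row] = spec.baseline + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        row += 1

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    annotation = SampleAnnotation.from_labels(sample_ids, labels)

    sides = {mid: m.side for mid, m in zip(module_genes, spec.modules)}
    relations: dict[str, str] = {}
    mids = list(module_genes)
    for i, ma in enumerate(mids):
        for mb in mids[i + 1:]:
            if spec.modules[i].delta == 0 or spec.modules[mids.index(mb)].delta == 0:
                continue
            rel = "EQUIVALENT" if sides[ma] == sides[mb] else "OPPOSITE"
            relations[f"{ma}|{mb}"] = rel
    path = [m for m in mids if sides[m] == "healthy_up" and _delta_of(spec, m) > 0]
    path += [m for m in mids if sides[m] == "disease_up" and _delta_of(spec, m) > 0]

    # In a two-class cohort, same-side modules are mutually equivalent by
    # construction, so the recoverable clusters are the per-side unions.
    equivalence_classes = {
        side: sorted(
            g
            for mid in mids
            if sides[mid] == side and _delta_of(spec, mid) > 0
            for g in module_genes[mid]
        )
        for side in _SIDES
    }
    equivalence_classes = {k: v for k, v in equivalence_classes.items() if v}
    path_classes = [
        {"side": side.replace("_up", ""), "genes": equivalence_classes[side]}
        for side in ("healthy_up", "disease_up")
        if side in equivalence_classes
    ]

    truth = {
        "modules": {mid: list(genes) for mid, genes in module_genes.items()},
        "module_sides": sides,
        "relations": relations,
        "path": path,
        "equivalence_classes": equivalence_classes,
        "path_classes": path_classes,
        "noise_genes": gene_ids[len(gene_ids) - spec.n_noise_genes:],
        "threshold": spec.baseline,
        "labels": dict(zip(sample_ids, labels)),
    }
    return matrix, annotation, truth


def _delta_of(spec: SyntheticSpec, mid: str) -> float:
    return spec.modules[int(mid[1:]) - 1].delta


def generate_trial_fixture(
    spec: SyntheticSpec, n_success: int = 5, n_failure: int = 5, n_contra: int = 2
) -> dict:
    """Build a cohort plus a targets table with planted vetting verdicts.

    The anchor is the first gene of the first healthy-side module.  Planted
    successes are disease-side module genes listed on both continuum paths
    (their anchor relation is OPPOSITE, i.e., anchor high => target low);
    planted failures are noise genes (on both paths, no implication) and
    disease-side genes missing from one path; planted contraindications are
    genes equivalent to the anchor (anchor high => target high).
    """
    spec.validate()
    healthy_mods = [k for k, m in enumerate(spec.modules) if m.side == "healthy_up"]
    disease_mods = [k for k, m in enumerate(spec.modules) if m.side == "disease_up"]
    if not healthy_mods or not disease_mods:
        raise ValueError("trial fixture needs at least one module per side")
    matrix, annotation, truth = generate_cohort(spec)
    module_genes = truth["modules"]
    anchor = module_genes[f"M{healthy_mods[0] + 1}"][0]

    disease_pool = [g for k in disease_mods for g in module_genes[f"M{k + 1}"]]
    anchor_pool = [g for g in module_genes[f"M{healthy_mods[0] + 1}"][1:]]
    noise_pool = list(truth["noise_genes"])
    if len(disease_pool) < n_success + max(n_failure - len(noise_pool), 0):
        raise ValueError("not enough disease-side genes for requested targets")
    if len(anchor_pool) < n_contra:
        raise ValueError("not enough anchor-module genes for contraindications")

    successes = disease_pool[:n_success]
    contras = anchor_pool[:n_contra]
    off_path = disease_pool[n_success:]
    failures: list[tuple[str, bool, bool]] = []
    for i in range(n_failure):
        if i < len(noise_pool):
            failures.append((noise_pool[i], True, True))  # on paths, no implication
        else:
            failures.append((off_path[i - len(noise_pool)], True, False))  # off one path

    rows = [(g, True, True) for g in successes]
    rows += [(g, True, True) for g in contras]
    rows += failures
    targets = pd.DataFrame(rows, columns=["gene_id", "on_path_emt", "on_path_fibrosis"])

    emt = {g for g, on_emt, _ in rows if on_emt}
    fibrosis = {g for g, _, on_fib in rows if on_fib}
    verdicts = {g: "predicted_success" for g in successes}
    verdicts.update({g: "contraindicated" for g in contras})
    verdicts.update({g: "predicted_failure" for g, *_ in failures})
    return {
        "matrix": matrix,
        "annotation": annotation,
        "truth": truth,
        "anchor": anchor,
        "targets": targets,
        "paths": {"emt": emt, "fibrosis": fibrosis},
        "verdicts": verdicts,
    }
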