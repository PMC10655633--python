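"""Synthetic cohorts with planted treatment-response signatures.

The generator emulates the statistical structure the analysis assumes: three
sample groups (responders, non-responders, healthy controls) with a small
set of signature genes whose expression is shifted away from the control
baseline in opposite directions in the two patient groups, and all remaining
genes pure Gaussian noise.  Group sizes default to the study design this
pipeline targets: 30 responders, 10 non-responders, 17 controls.

Ground truth (which genes were planted) is returned separately and written
to its own manifest file, never into the expression matrix, so downstream
stages cannot read the answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import (
    GROUP_CONTROL,
    GROUP_NONRESPONDER,
    GROUP_RESPONDER,
    CohortLabels,
    encode_labels,
)
from .rules import RuleSet

#: responders shifted down, non-responders up, controls at baseline
DIRECTION_RESP_DOWN = "resp_down_nonresp_up"
#: mirrored variant for robustness tests
DIRECTION_RESP_UP = "resp_up_nonresp_down"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the shift (in noise-sd units) applied to each planted
    gene in each patient group, so the responder/non-responder group-mean
    difference is ``2 * effect_size``.
    """

    n_responders: int = 30
    n_nonresponders: int = 10
    n_controls: int = 17
    n_genes: int = 2000
    n_signature: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    direction: str = DIRECTION_RESP_DOWN
    seed: int = 0

    def __post_init__(self):
        for name in ("n_responders", "n_nonresponders", "n_controls", "n_genes", "n_signature"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_signature > self.n_genes:
            raise ConfigurationError(
                f"n_signature ({self.n_signature}) cannot exceed n_genes ({self.n_genes})"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.direction not in (DIRECTION_RESP_DOWN, DIRECTION_RESP_UP):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the signature genes and, for boolean fixtures, the DNF."""

    signature_gene_ids: tuple[str, ...] = ()
    planted_dnf: RuleSet | None = None
    seed: int = 0


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, CohortLabels, GroundTruth]:
    """Draw an expression matrix, labels and ground truth from the config.

    Non-signature genes are i.i.d. ``N(0, noise_sd^2)`` in every group.
    Signature genes keep controls at baseline (mean 0) and shift responders
    and non-responders by ``-effect_size`` / ``+effect_size`` (default
    direction; mirrored if configured).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_responders + config.n_nonresponders + config.n_controls

    width = max(2, len(str(config.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    sample_ids = (
        [f"R{i + 1:02d}" for i in range(config.n_responders)]
        + [f"N{i + 1:02d}" for i in range(config.n_nonresponders)]
        + [f"C{i + 1:02d}" for i in range(config.n_controls)]
    )
    groups = (
        [GROUP_RESPONDER] * config.n_responders
        + [GROUP_NONRESPONDER] * config.n_nonresponders
        + [GROUP_CONTROL] * config.n_controls
    )

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    sig_rows = np.sort(rng.choice(config.n_genes, size=config.n_signature, replace=False))
    sign = -1.0 if config.direction == DIRECTION_RESP_DOWN else 1.0
    resp = slice(0, config.n_responders)
    nonresp = slice(config.n_responders, config.n_responders + config.n_nonresponders)
    values[np.ix_(sig_rows, range(*resp.indices(n_samples)))] += sign * config.effect_size
    values[np.ix_(sig_rows, range(*nonresp.indices(n_samples)))] -= sign * config.effect_size

    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    labels = encode_labels(dict(zip(sample_ids, groups)), sample_ids)
    truth = GroundTruth(
        signature_gene_ids=tuple(gene_ids[i] for i in sig_rows), seed=config.seed
    )
    return matrix, labels, truth


def generate_boolean_fixture(
    n_samples: int,
    planted_dnf: RuleSet,
    n_noise_concepts: int = 0,
    label_noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Draw a boolean concept matrix whose class is a planted DNF.

    Concept columns (the DNF's literals plus ``noise01`` ... padding) are
    i.i.d. Bernoulli(0.5); the class vector is the DNF evaluated on its own
    literals and then flipped independently with probability ``label_noise``.
    """
    if planted_dnf is None or not planted_dnf.rules:
        raise ConfigurationError("planted_dnf must contain at least one rule")
    if not 0.0 <= label_noise < 0.5:
        raise ConfigurationError(f"label_noise must be in [0, 0.5), got {label_noise}")
    rng = np.random.default_rng(seed)
    concepts = planted_dnf.concepts
    width = max(2, len(str(max(n_noise_concepts, 1))))
    noise_cols = [f"noise{i + 1:0{width}d}" for i in range(n_noise_concepts)]
    cols = concepts + noise_cols
    data = rng.random(size=(n_samples, len(cols))) < 0.5
    C = pd.DataFrame(data, columns=cols)
    y = planted_dnf.predict(C).astype(int)
    if label_noise > 0:
        flips = rng.random(n_samples) < label_noise
        y = np.where(flips, 1 - y, y)
    truth = GroundTruth(planted_dnf=planted_dnf, seed=seed)
    return C, y, truth


def write_fixture(
    matrix: pd.DataFrame, labels: CohortLabels, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write the matrix, label table and ground-truth manifest as TSV/text.

    The files round-trip losslessly through :mod:`refsel.io`'s readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "labels": directory / "labels.tsv",
        "truth": directory / "truth.tsv",
    }
    with open(paths["matrix"], "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.columns) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in labels.groups.items():
            fh.write(f"{sample}\t{group}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(f"signature_genes\t{','.join(truth.signature_gene_ids)}\n")
        fh.write(f"seed\t{truth.seed}\n")
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    """Read back a ground-truth manifest written by :func:`write_fixture`."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, value = line.partition("\t")
            fields[key] = value
    genes = tuple(g for g in fields.get("signature_genes", "").split(",") if g)
    return GroundTruth(signature_gene_ids=genes, seed=int(fields.get("seed", 0)))


def permute_labels(labels: CohortLabels, seed: int) -> CohortLabels:
    """Randomly permute the patient class labels, leaving controls fixed.

    Used for null-calibration experiments: group sizes are conserved, but
    any gene/outcome association is destroyed.
    """
    rng = np.random.default_rng(seed)
    patients = labels.patient_ids
    permuted = list(rng.permutation(labels.groups.loc[patients].to_numpy()))
    groups = labels.groups.to_dict()
    groups.update(dict(zip(patients, permuted)))
    return encode_labels(groups, list(labels.groups.index))
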