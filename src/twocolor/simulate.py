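"""Synthetic dual-color datasets with known ground truth.

The generator realizes the additive log2-scale model the genewise analyses
assume: for probe g on channel c,

    y[g, c] = mu[g] + tau[g, group(c)] + b[g, unit(c)]
              + alpha[g, array(c)] + dye_shift(dye(c)) + eps[g, c]

with independent Gaussian components.  Array (spot) effects are drawn per
(probe, array) — the genewise nuisance the ratio model estimates — not as a
single array-wide shift.  Three standard hybridization topologies are
generated:

``two-group-paired``
    Every array co-hybridizes the two groups (technical replication of one
    comparison, dye-swapped halfway for balance) — a reference-style
    benchmark without biological variation.
``factorial-replicated``
    Units (e.g. cell lines) crossed with treatments; within each replicate
    set every treatment pair is hybridized in both dye orientations
    (dye-swap duplicate arrays), so each sample is measured once per dye
    and every set carries a dye-balanced copy of the factorial.
``interwoven-loop``
    Samples chained around a loop g -> g+1 so each unit is hybridized
    exactly twice, once per dye — the design type used for cohorts with
    one array pair per subject.

One root seed expands into per-component substreams, so enlarging the probe
count leaves the values of existing probes unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ChannelKey, DesignRow, HybridizationDesign
from .preprocess import ExpressionMatrix, read_channels

TOPOLOGY_TWO_GROUP_PAIRED = "two-group-paired"
TOPOLOGY_FACTORIAL = "factorial-replicated"
TOPOLOGY_LOOP = "interwoven-loop"
_TOPOLOGIES = (TOPOLOGY_TWO_GROUP_PAIRED, TOPOLOGY_FACTORIAL, TOPOLOGY_LOOP)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Standard deviations are in log2 units.  ``fraction_de`` of probes are
    differentially expressed; their per-group shifts are drawn N(0,
    ``effect_sd``) (``effect="normal"``) or laid out on a fixed ladder of
    total span ``effect_size`` (``effect="fixed"``).
    """

    seed: int
    n_probes: int = 1000
    topology: str = TOPOLOGY_TWO_GROUP_PAIRED
    n_groups: int = 2
    n_units_per_group: int = 1
    technical_replicates: int = 8
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    fraction_de: float = 0.2
    effect: str = "normal"
    effect_sd: float = 0.5
    effect_size: float = 0.5
    sigma_noise: float = 0.25
    sigma_array: float = 0.1
    sigma_unit: float = 0.0
    dye_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("baseline_sd", "sigma_noise", "sigma_array", "sigma_unit", "effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_de <= 1.0:
            raise ValueError("fraction_de must lie in [0, 1]")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.effect not in ("normal", "fixed"):
            raise ValueError("effect must be 'normal' or 'fixed'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SimTruth:
    """Ground-truth parameter values aligned with the emitted matrix.

    ``probes``: per-probe mu, de flag and per-group tau columns
    (``tau[<group>]``); ``array_effects``: probes x arrays alpha;
    ``unit_effects``: probes x units biological effects.
    """

    probes: pd.DataFrame
    array_effects: pd.DataFrame
    unit_effects: pd.DataFrame

    @property
    def de_mask(self) -> np.ndarray:
        return self.probes["de"].to_numpy(dtype=bool)


def make_design(
    topology: str,
    n_groups: int = 2,
    n_units_per_group: int = 1,
    technical_replicates: int = 8,
) -> HybridizationDesign:
    """Generate a standard hybridization topology (see module docstring).

    For ``two-group-paired``, ``technical_replicates`` is the number of
    arrays.  For ``factorial-replicated``, ``n_units_per_group`` is the
    number of units crossed with all treatments and ``technical_replicates``
    the number of replicate sets (use an even count for dye balance).  For
    ``interwoven-loop``, each of the ``n_groups * n_units_per_group`` units
    appears on exactly two arrays and ``technical_replicates`` is ignored
    (the duplicate labeling is inherent).
    """
    if topology == TOPOLOGY_TWO_GROUP_PAIRED:
        if n_groups != 2:
            raise ValueError("two-group-paired requires n_groups = 2")
        if technical_replicates < 1:
            raise ValueError("need at least one array")
        n_arrays = technical_replicates
        rows = []
        for a in range(n_arrays):
            array_id = f"A{a + 1:02d}"
            swap = a >= (n_arrays + 1) // 2  # dye-swap the second half
            rep = 2 if swap else 1
            dyes = ("Cy5", "Cy3") if swap else ("Cy3", "Cy5")
            for g, dye in zip((0, 1), dyes):
                rows.append(
                    DesignRow(
                        channel=ChannelKey(array_id, dye),
                        sample_id=f"G{g + 1}_U1",
                        treatment=f"G{g + 1}",
                        unit=f"G{g + 1}_U1",
                        replicate_set=rep,
                    )
                )
        return HybridizationDesign(rows)

    if topology == TOPOLOGY_FACTORIAL:
        if n_groups < 2 or n_groups % 2:
            raise ValueError("factorial-replicated requires an even n_groups >= 2")
        if n_units_per_group < 1 or technical_replicates < 1:
            raise ValueError("need at least one unit and one replicate set")
        half = n_groups // 2
        rows = []
        array_no = 0
        for s in range(1, technical_replicates + 1):
            for u in range(n_units_per_group):
                unit = f"U{u + 1}"
                for i in range(half):
                    g_a, g_b = 2 * i, 2 * i + 1
                    # each treatment pair is hybridized in both dye
                    # orientations within a set (dye-swap duplicate arrays),
                    # so every sample is measured once per dye
                    for dye_a, dye_b in (("Cy3", "Cy5"), ("Cy5", "Cy3")):
                        array_no += 1
                        array_id = f"A{array_no:02d}"
                        for g, dye in ((g_a, dye_a), (g_b, dye_b)):
                            rows.append(
                                DesignRow(
                                    channel=ChannelKey(array_id, dye),
                                    sample_id=f"{unit}_T{g + 1}_R{s}",
                                    treatment=f"T{g + 1}",
                                    unit=unit,
                                    replicate_set=s,
                                )
                            )
        return HybridizationDesign(rows)

    if topology == TOPOLOGY_LOOP:
        if n_groups < 3:
            raise ValueError("interwoven-loop requires n_groups >= 3")
        if n_units_per_group < 1:
            raise ValueError("need at least one unit per group")
        # sample sequence cycling through the groups; consecutive samples share an array
        seq = [
            (g, f"G{g + 1}_U{j + 1}")
            for j in range(n_units_per_group)
            for g in range(n_groups)
        ]
        n = len(seq)
        rows = []
        for a in range(n):
            array_id = f"A{a + 1:02d}"
            (g3, u3) = seq[a]
            (g5, u5) = seq[(a + 1) % n]
            for (g, unit), dye in (((g3, u3), "Cy3"), ((g5, u5), "Cy5")):
                rows.append(
                    DesignRow(
                        channel=ChannelKey(array_id, dye),
                        sample_id=unit,
                        treatment=f"G{g + 1}",
                        unit=unit,
                        replicate_set=None,
                    )
                )
        return HybridizationDesign(rows)

    raise ValueError(f"unknown topology {topology!r}")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, HybridizationDesign, SimTruth]:
    """Draw one dataset (log2-scale matrix, design, ground truth) from ``config``."""
    design = make_design(
        config.topology,
        config.n_groups,
        config.n_units_per_group,
        config.technical_replicates,
    )
    groups = design.treatments
    units = design.units
    arrays = design.arrays
    n_probes = config.n_probes

    root = np.random.SeedSequence(config.seed)
    rng_mu, rng_de, rng_tau, rng_unit, rng_array, rng_eps = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    mu = rng_mu.normal(config.baseline_mean, config.baseline_sd, n_probes)
    de = rng_de.uniform(size=n_probes) < config.fraction_de
    if config.effect == "normal":
        tau = rng_tau.normal(0.0, config.effect_sd, (n_probes, len(groups)))
    else:
        ladder = np.linspace(-0.5, 0.5, len(groups)) * config.effect_size
        tau = np.tile(ladder, (n_probes, 1))
    tau = tau * de[:, None]
    b = rng_unit.normal(0.0, config.sigma_unit, (n_probes, len(units)))
    alpha = rng_array.normal(0.0, config.sigma_array, (n_probes, len(arrays)))
    eps = rng_eps.normal(0.0, config.sigma_noise, (n_probes, len(design)))

    group_idx = {g: i for i, g in enumerate(groups)}
    unit_idx = {u: i for i, u in enumerate(units)}
    array_idx = {a: i for i, a in enumerate(arrays)}

    width = max(5, len(str(n_probes)))
    probe_ids = np.array([f"P{i + 1:0{width}d}" for i in range(n_probes)], dtype=object)

    values = np.empty((n_probes, len(design)))
    for c, row in enumerate(design.rows):
        values[:, c] = (
            mu
            + tau[:, group_idx[row.treatment]]
            + b[:, unit_idx[row.unit]]
            + alpha[:, array_idx[row.channel.array_id]]
            + (config.dye_effect if row.channel.dye == "Cy5" else 0.0)
            + eps[:, c]
        )

    matrix = ExpressionMatrix(probe_ids, design.channels, values, log2=True)
    probes = pd.DataFrame(
        {"mu": mu, "de": de, **{f"tau[{g}]": tau[:, i] for g, i in group_idx.items()}},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = SimTruth(
        probes=probes,
        array_effects=pd.DataFrame(alpha, index=probes.index, columns=arrays),
        unit_effects=pd.DataFrame(b, index=probes.index, columns=units),
    )
    return matrix, design, truth


def write_dataset(
    matrix: ExpressionMatrix,
    design: HybridizationDesign,
    truth: SimTruth | None,
    directory,
) -> dict[str, Path]:
    """Write matrix/design/truth as TSV files; returns the paths written.

    ``expression.tsv`` round-trips exactly through
    :func:`twocolor.preprocess.read_channels` (wide-tsv dialect).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "design": directory / "design.tsv",
    }
    # %.17g keeps the text round trip exact to the last bit
    matrix.to_frame().to_csv(paths["expression"], sep="\t", float_format="%.17g")
    design.write_tsv(paths["design"])
    if truth is not None:
        paths["truth_probes"] = directory / "truth_probes.tsv"
        paths["truth_array_effects"] = directory / "truth_array_effects.tsv"
        paths["truth_unit_effects"] = directory / "truth_unit_effects.tsv"
        truth.probes.to_csv(paths["truth_probes"], sep="\t", float_format="%.17g")
        truth.array_effects.to_csv(paths["truth_array_effects"], sep="\t", float_format="%.17g")
        truth.unit_effects.to_csv(paths["truth_unit_effects"], sep="\t", float_format="%.17g")
    return paths


def read_dataset(directory) -> tuple[ExpressionMatrix, HybridizationDesign]:
    """Read back a dataset written by :func:`write_dataset` (log2 scale)."""
    directory = Path(directory)
    matrix = read_channels(directory / "expression.tsv", dialect="wide-tsv")
    matrix.log2 = True  # the simulator writes log2-scale values
    design = HybridizationDesign.read_tsv(directory / "design.tsv")
    return matrix, design
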