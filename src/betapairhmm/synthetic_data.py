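"""Synthetic samples drawn from the generative pair-HMM.

The simulator emulates the structure of a two-probes-per-gene methylation
array: per probe pair it draws k1 from the pair class's initial distribution
and k2 from the transition row T[k1, .], then emits beta-values from the
state emission distributions.  Genes are laid out on a synthetic chromosome
in 20 kb blocks, each carrying one CpG island, with probe positions chosen
so that interval-based location classification reproduces the intended
classes exactly (island probes inside the island, shore probes a few hundred
bp outside it, outside probes 6 kb away).  Ground-truth states are returned
for calibration studies.

The bundled parameter profiles are invented, well-separated fixtures (the
low state concentrates near 0, the symmetric medium state at 0.5, the high
state near 1); the "tumor-like" profile shifts outside-region mass from the
low state toward medium/high relative to "normal-like", echoing the
tissue contrasts the model is meant to expose.  They are fixtures, not
estimates from any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    PAIR_CLASSES,
    BetaParams,
    ClassEmissions,
    ModelError,
    PairClassModel,
    SampleModel,
    allowed_states,
)

_BLOCK = 20_000  # bp per synthetic gene block
_ISLAND = (1_000, 2_000)  # island interval within a block (half-open)
#: probe offsets within a block per location class: (pair positions, singleton)
_OFFSETS = {
    "I": ((1_200, 1_400), 1_300),
    "S": ((2_500, 3_000), 2_700),
    "O": ((8_000, 8_500), 8_200),
}
_CHROM = "chr1"

#: Default mix of pair classes, loosely following the 27k design where
#: island probes dominate and mixed island/shore pairs are a minority.
DEFAULT_PAIR_FRACTIONS = {"II": 0.50, "SS": 0.20, "OO": 0.15, "SI": 0.15}
#: Default mix of single-probe genes across location classes.
DEFAULT_SINGLETON_FRACTIONS = {"I": 0.50, "S": 0.22, "O": 0.28}

_EMISSIONS = {
    "I": {"L": (1.5, 18.0), "M": (8.0, 8.0)},
    "S": {"L": (1.5, 18.0), "M": (8.0, 8.0), "H": (15.0, 1.8)},
    "O": {"L": (1.5, 18.0), "M": (8.0, 8.0), "H": (15.0, 1.8)},
}

_PROFILES = {
    "normal-like": {
        "II": ([0.85, 0.15], [[0.95, 0.05], [0.30, 0.70]]),
        "SS": (
            [0.60, 0.30, 0.10],
            [[0.80, 0.15, 0.05], [0.20, 0.60, 0.20], [0.05, 0.25, 0.70]],
        ),
        "OO": (
            [0.12, 0.44, 0.44],
            [[0.60, 0.25, 0.15], [0.10, 0.70, 0.20], [0.05, 0.25, 0.70]],
        ),
        "SI": (
            [0.60, 0.30, 0.10],
            [[0.90, 0.10], [0.30, 0.70], [0.20, 0.80]],
        ),
    },
    "tumor-like": {
        "II": ([0.70, 0.30], [[0.90, 0.10], [0.25, 0.75]]),
        "SS": (
            [0.45, 0.35, 0.20],
            [[0.75, 0.18, 0.07], [0.15, 0.65, 0.20], [0.05, 0.30, 0.65]],
        ),
        "OO": (
            [0.20, 0.55, 0.25],
            [[0.50, 0.35, 0.15], [0.08, 0.75, 0.17], [0.05, 0.35, 0.60]],
        ),
        "SI": (
            [0.55, 0.32, 0.13],
            [[0.88, 0.12], [0.28, 0.72], [0.22, 0.78]],
        ),
    },
}


def default_model(profile: str = "normal-like", sample_id: str | None = None) -> SampleModel:
    """A fully specified 37-parameter fixture model.

    ``profile`` is "normal-like" or "tumor-like"; the two share emission
    shapes (L=Beta(1.5,18), M=Beta(8,8), H=Beta(15,1.8)) and differ in
    mixture/transition probabilities, most strongly in the outside (O)
    class where the tumor-like profile makes medium methylation dominant.
    """
    if profile not in _PROFILES:
        raise ModelError(
            f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}"
        )
    emissions = {
        a: ClassEmissions(a, {k: BetaParams(*p) for k, p in by_state.items()})
        for a, by_state in _EMISSIONS.items()
    }
    pair_models = {
        pc: PairClassModel(pc, np.array(om), np.array(T))
        for pc, (om, T) in _PROFILES[profile].items()
    }
    return SampleModel(sample_id or profile, emissions, pair_models)


@dataclass
class SimSpec:
    """Specification of one simulated sample.

    ``n_pairs`` maps pair class to the number of two-probe genes;
    ``n_singletons`` maps location class to the number of one-probe genes
    (these contribute to marginal mixture fitting only).  The same seed
    always reproduces the same sample bit for bit.
    """

    model: SampleModel
    n_pairs: dict[str, int] = field(
        default_factory=lambda: {"II": 1000, "SS": 400, "OO": 300, "SI": 300}
    )
    n_singletons: dict[str, int] = field(
        default_factory=lambda: {"I": 220, "S": 100, "O": 120}
    )
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self):
        for pc, n in self.n_pairs.items():
            if pc not in PAIR_CLASSES:
                raise ModelError(f"unknown pair class {pc!r}")
            if n < 0:
                raise ValueError("pair counts must be >= 0")
        for a, n in self.n_singletons.items():
            if a not in ("I", "S", "O"):
                raise ModelError(f"unknown location class {a!r}")
            if n < 0:
                raise ValueError("singleton counts must be >= 0")


def split_pair_counts(total: int, fractions=None) -> dict[str, int]:
    """Split a total gene count into per-pair-class counts."""
    fr = fractions or DEFAULT_PAIR_FRACTIONS
    counts = {pc: int(round(total * f)) for pc, f in fr.items()}
    drift = total - sum(counts.values())
    counts["II"] += drift
    return counts


def split_singleton_counts(total: int, fractions=None) -> dict[str, int]:
    fr = fractions or DEFAULT_SINGLETON_FRACTIONS
    counts = {a: int(round(total * f)) for a, f in fr.items()}
    counts["I"] += total - sum(counts.values())
    return counts


def _draw_states(
    rng: np.random.Generator, omega: np.ndarray, T: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    k1 = rng.choice(len(omega), size=n, p=omega)
    u = rng.random(n)
    cum = np.cumsum(T, axis=1)
    k2 = (u[:, None] > cum[k1]).sum(axis=1)
    return k1, k2


def _emit(rng: np.random.Generator, em: ClassEmissions, k: np.ndarray) -> np.ndarray:
    a, b = em.shape_arrays()
    x = rng.beta(a[k], b[k])
    return np.clip(x, 1e-12, 1.0 - 1e-12)


def simulate_sample(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one sample from the generative model.

    Returns ``(betas, annotations, truth)``: a probes x 1 beta matrix, a
    probe annotation table (probe_id, gene_id, chromosome, position,
    location_class), and the ground-truth joint states per gene (columns
    gene_id, pair_class, k1, k2; singleton genes have pair_class = the
    location class and k2 = "").  States in ``truth`` follow the model's
    pair-class order, i.e. for (S,I) genes k1 is the shore probe's state
    even though the island probe comes first on the chromosome.
    """
    sm = spec.model
    root = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            list(PAIR_CLASSES) + ["I", "S", "O"],
            root.spawn(len(PAIR_CLASSES) + 3),
        )
    }

    probe_ids: list[str] = []
    gene_ids: list[str] = []
    positions: list[int] = []
    classes: list[str] = []
    values: list[float] = []
    truth_rows: list[dict] = []
    block = 0

    for pc in PAIR_CLASSES:
        n = spec.n_pairs.get(pc, 0)
        if n == 0:
            continue
        if pc not in sm.pair_models:
            raise ModelError(f"model lacks pair class {pc}")
        rng = streams[pc]
        pm = sm.pair_models[pc]
        em1, em2 = sm.emissions_for_pair(pc)
        k1, k2 = _draw_states(rng, pm.omega_init, pm.transition, n)
        x1 = _emit(rng, em1, k1)
        x2 = _emit(rng, em2, k2)
        s1, s2 = pm.states1, pm.states2
        for i in range(n):
            gene = f"g{pc}_{block:06d}"
            base = block * _BLOCK
            if pc == "SI":
                # island probe precedes the shore probe on the chromosome;
                # pair assembly swaps (I,S) back into (S,I)
                layout = [
                    ("I", _OFFSETS["I"][0][0], x2[i]),
                    ("S", _OFFSETS["S"][0][0], x1[i]),
                ]
            else:
                a = pc[0]
                layout = [
                    (a, _OFFSETS[a][0][0], x1[i]),
                    (a, _OFFSETS[a][0][1], x2[i]),
                ]
            for slot, (cls, off, val) in enumerate(layout, start=1):
                probe_ids.append(f"{gene}_p{slot}")
                gene_ids.append(gene)
                positions.append(base + off)
                classes.append(cls)
                values.append(val)
            truth_rows.append(
                {
                    "gene_id": gene,
                    "pair_class": pc,
                    "k1": s1[k1[i]],
                    "k2": s2[k2[i]],
                }
            )
            block += 1

    for a in ("I", "S", "O"):
        n = spec.n_singletons.get(a, 0)
        if n == 0:
            continue
        rng = streams[a]
        em = sm.emissions[a]
        # marginal state prior for a lone probe: the class's own-pair
        # initial distribution
        own_pair = {"I": "II", "S": "SS", "O": "OO"}[a]
        omega = sm.pair_models[own_pair].omega_init
        k = rng.choice(len(omega), size=n, p=omega)
        x = _emit(rng, em, k)
        states = allowed_states(a)
        for i in range(n):
            gene = f"s{a}_{block:06d}"
            probe_ids.append(f"{gene}_p1")
            gene_ids.append(gene)
            positions.append(block * _BLOCK + _OFFSETS[a][1])
            classes.append(a)
            values.append(x[i])
            truth_rows.append(
                {"gene_id": gene, "pair_class": a, "k1": states[k[i]], "k2": ""}
            )
            block += 1

    betas = pd.DataFrame({spec.sample_id: values}, index=pd.Index(probe_ids, name="probe_id"))
    annotations = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_ids,
            "chromosome": _CHROM,
            "position": positions,
            "location_class": classes,
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "pair_class", "k1", "k2"])
    return betas, annotations, truth


def islands_bed_frame(annotations: pd.DataFrame) -> pd.DataFrame:
    """CpG-island intervals matching a simulated annotation table.

    Every 20 kb gene block carries one island at the same block offset, so
    the intervals can be reconstructed from the probe positions; writing
    them to BED lets the annotation round-trip through interval-based
    classification.
    """
    blocks = sorted(set(int(p) // _BLOCK for p in annotations["position"]))
    return pd.DataFrame(
        {
            "chrom": _CHROM,
            "start": [b * _BLOCK + _ISLAND[0] for b in blocks],
            "end": [b * _BLOCK + _ISLAND[1] for b in blocks],
        }
    )
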