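"""Class-structured synthetic data: sequences, domain annotations and PSSMs.

The generator emulates the statistical structure the feature families assume
in real data, with a class-dependent signal in each family:

* **Domains** — each catalog domain is assigned independently, with a higher
  per-domain probability for ECM proteins than for negatives. With the
  defaults an ECM protein carries about three catalog domains (as real
  matrisome proteins carry a handful of hallmark domains) while negatives are
  mostly domain-free.
* **Composition** — ECM sequences are enriched in glycine, proline and
  cysteine (the collagen-like bias of real ECM proteins): the probability
  mass of the enriched residue set is scaled by ``1 + composition_shift``
  and renormalized. This shifts the physicochemical means.
* **PSSM** — log-odds scores are drawn from a rounded normal and clipped to
  [-10, 10] (PSI-BLAST's typical range); for ECM proteins a constant
  ``pssm_signal`` offset is added to a fixed set of signal columns,
  emulating class-specific conservation.

What the generator does **not** emulate: real domain co-occurrence
structure, sequence homology between proteins, position-dependent PSSM
structure along the sequence, and label noise. Performance on this data
therefore bounds pipeline correctness, not real-world accuracy.

All parameters and the per-protein ground truth are serialized to
``truth.json`` so downstream checks can assert recovery without re-deriving
the generator.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .io import AA_ORDER, ECM, NON_ECM, DomainCatalog, PSSM, ProteinRecord

#: Residues enriched in positive-class sequences (collagen-like bias).
ENRICHED_RESIDUES = ("G", "P", "C")
#: PSSM columns that carry the positive-class score offset.
SIGNAL_RESIDUES = ("G", "P", "C", "W", "Y")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    The default class sizes reproduce the ~1:21 imbalance of curated ECM
    training data at desk scale.
    """

    n_pos: int = 100
    n_neg: int = 2100
    seq_len_range: tuple[int, int] = (50, 200)
    p_domain_pos: float = 0.05
    p_domain_neg: float = 0.002
    composition_shift: float = 0.5
    pssm_signal: float = 2.0
    p_unknown: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one protein per class")
        if not (0 <= self.p_domain_pos <= 1 and 0 <= self.p_domain_neg <= 1):
            raise ValueError("domain probabilities must lie in [0, 1]")
        if self.seq_len_range[0] < 4:
            raise ValueError("minimum sequence length is 4 (PSSM descriptor precondition)")
        if self.composition_shift < 0 or self.pssm_signal < 0:
            raise ValueError("signal strengths must be non-negative")

    @classmethod
    def null(cls, n_pos: int = 100, n_neg: int = 200, seed: int = 0, **kw) -> "SimConfig":
        """No class signal in any feature family (chance-level dataset)."""
        return cls(
            n_pos=n_pos, n_neg=n_neg,
            p_domain_pos=0.02, p_domain_neg=0.02,
            composition_shift=0.0, pssm_signal=0.0,
            seed=seed, **kw,
        )

    @classmethod
    def moderate(cls, n_pos: int = 50, n_neg: int = 1050, seed: int = 0, **kw) -> "SimConfig":
        """Overlapping classes for experiments about imbalance handling.

        Signals are weak enough that a classifier cannot saturate, so the
        damage done by class imbalance — and the repair by the ensemble —
        is visible in the metrics.
        """
        return cls(
            n_pos=n_pos, n_neg=n_neg,
            p_domain_pos=0.02, p_domain_neg=0.006,
            composition_shift=0.15, pssm_signal=0.5,
            seed=seed, **kw,
        )


@dataclasses.dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus its generating configuration."""

    records: list[ProteinRecord]
    labels: pd.Series                 # protein_id -> ECM / nonECM
    annotations: dict[str, set[str]]
    pssms: dict[str, PSSM]
    config: SimConfig
    catalog: DomainCatalog


def _residue_probs(shift: float, p_unknown: float) -> tuple[list[str], np.ndarray]:
    letters = list(AA_ORDER) + ["X"]
    probs = np.full(20, (1.0 - p_unknown) / 20)
    for res in ENRICHED_RESIDUES:
        probs[AA_ORDER.index(res)] *= 1.0 + shift
    probs *= (1.0 - p_unknown) / probs.sum()
    return letters, np.append(probs, p_unknown)


def _draw_sequence(rng: np.random.Generator, length: int, shift: float, p_unknown: float) -> str:
    letters, probs = _residue_probs(shift, p_unknown)
    seq = rng.choice(letters, size=length, p=probs)
    # physicochemical means need at least one canonical residue
    if all(c == "X" for c in seq):
        seq[0] = "A"
    return "".join(seq)


def _draw_scores(rng: np.random.Generator, length: int, signal: float) -> np.ndarray:
    raw = rng.normal(0.0, 3.0, size=(length, 20))
    if signal > 0:
        for res in SIGNAL_RESIDUES:
            raw[:, AA_ORDER.index(res)] += signal
    return np.clip(np.rint(raw), -10, 10).astype(np.int64)


def generate(config: SimConfig, catalog: DomainCatalog | None = None) -> SyntheticDataset:
    """Generate the dataset in memory (deterministic in ``config.seed``)."""
    catalog = catalog or eio.read_domain_catalog()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_len_range
    records, ids, labels = [], [], []
    annotations: dict[str, set[str]] = {}
    pssms: dict[str, PSSM] = {}
    spec = [(ECM, config.n_pos, config.p_domain_pos, config.composition_shift, config.pssm_signal),
            (NON_ECM, config.n_neg, config.p_domain_neg, 0.0, 0.0)]
    for label, count, p_domain, shift, signal in spec:
        for i in range(count):
            pid = f"{'POS' if label == ECM else 'NEG'}{i + 1:05d}"
            length = int(rng.integers(lo, hi + 1))
            rec = ProteinRecord(id=pid, sequence=_draw_sequence(rng, length, shift, config.p_unknown))
            assigned = {acc for acc in catalog.accessions if rng.random() < p_domain}
            if assigned:
                annotations[pid] = assigned
            pssms[pid] = PSSM(protein_id=pid, scores=_draw_scores(rng, length, signal))
            records.append(rec)
            ids.append(pid)
            labels.append(label)
    return SyntheticDataset(
        records=records,
        labels=pd.Series(labels, index=ids, name="label"),
        annotations=annotations,
        pssms=pssms,
        config=config,
        catalog=catalog,
    )


def format_pssm(pssm: PSSM) -> str:
    """Render a PSSM in the PSI-BLAST ASCII dialect the parser consumes."""
    lines = ["", "Last position-specific scoring matrix computed (synthetic profile)", ""]
    header = " " * 11 + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER)
    lines.append(header)
    for i, row in enumerate(pssm.scores, start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        percents = " ".join("  0" for _ in range(20))
        lines.append(f"{i:5d} A  {scores}  {percents}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1347     0.3240", ""]
    return "\n".join(lines)


def generate_pssm(sequence: str, config: SimConfig, rng: np.random.Generator,
                  positive: bool = False, protein_id: str = "synthetic") -> str:
    """ASCII PSSM content for one sequence; round-trips through the parser."""
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4 residues has no PSSM descriptor")
    scores = _draw_scores(rng, len(sequence), config.pssm_signal if positive else 0.0)
    return format_pssm(PSSM(protein_id=protein_id, scores=scores))


def generate_dataset(config: SimConfig, out_dir: str | Path,
                     catalog: DomainCatalog | None = None) -> dict[str, Path]:
    """Generate and write the full synthetic file set.

    Writes ``sequences.fasta``, ``annotations.tsv``, ``labels.tsv``,
    ``dataset.tsv`` (the labeled-table mirror), ``pssm/<id>.pssm`` and
    ``truth.json``; byte-identical for identical configurations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pssm").mkdir(exist_ok=True)
    data = generate(config, catalog=catalog)

    eio.write_fasta(data.records, out_dir / "sequences.fasta")
    with open(out_dir / "annotations.tsv", "w") as fh:
        fh.write("protein_id\taccession\n")
        for rec in data.records:
            for acc in sorted(data.annotations.get(rec.id, ())):
                fh.write(f"{rec.id}\t{acc}\n")
    data.labels.rename_axis("protein_id").reset_index().to_csv(
        out_dir / "labels.tsv", sep="\t", index=False
    )
    eio.write_labeled_dataset(
        pd.DataFrame({
            "UniprotID": [r.id for r in data.records],
            "Class": data.labels.values,
            "FastaSequence": [r.sequence for r in data.records],
        }),
        out_dir / "dataset.tsv",
    )
    for rec in data.records:
        (out_dir / "pssm" / f"{rec.id}.pssm").write_text(format_pssm(data.pssms[rec.id]))
    truth = {
        "config": dataclasses.asdict(config),
        "enriched_residues": list(ENRICHED_RESIDUES),
        "signal_residues": list(SIGNAL_RESIDUES),
        "proteins": {
            rec.id: {
                "label": str(data.labels[rec.id]),
                "length": rec.length,
                "n_domains": len(data.annotations.get(rec.id, ())),
            }
            for rec in data.records
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "fasta": out_dir / "sequences.fasta",
        "annotations": out_dir / "annotations.tsv",
        "labels": out_dir / "labels.tsv",
        "dataset": out_dir / "dataset.tsv",
        "pssm_dir": out_dir / "pssm",
        "truth": out_dir / "truth.json",
    }


def generate_dataset_mirror(n_pos: int, n_neg: int, seed: int = 0,
                            seq_len_range: tuple[int, int] = (30, 60)) -> pd.DataFrame:
    """A labeled-table mirror (UniprotID, Class, FastaSequence) of given sizes.

    Sequences are short unbiased draws — this is for dataset-arithmetic
    checks at realistic class counts, not for feature-level signal.
    """
    rng = np.random.default_rng(seed)
    lo, hi = seq_len_range
    rows = []
    letters = list(AA_ORDER)
    for label, count, prefix in ((ECM, n_pos, "POS"), (NON_ECM, n_neg, "NEG")):
        lengths = rng.integers(lo, hi + 1, size=count)
        for i, length in enumerate(lengths):
            seq = "".join(rng.choice(letters, size=int(length)))
            rows.append({"UniprotID": f"{prefix}{i + 1:05d}", "Class": label,
                         "FastaSequence": seq})
    return pd.DataFrame(rows)
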