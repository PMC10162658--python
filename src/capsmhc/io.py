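"""Readers and writers for the benchmark table dialects, plus run config.

Three tab-separated dialects map onto :class:`BindingRecord`:

``iedb_benchmark``
    columns (date, reference, allele, peptide_length, measurement_kind,
    peptide, value); ``measurement_kind`` "ic50" or "binary".
``anthem``
    columns (allele, peptide, label) with a binary label.
``internal``
    columns (allele, peptide, measurement_kind, value).

Malformed rows are collected into a report with line numbers rather than
aborting the read; peptides longer than 15 residues (the encoder cap) are
skipped and counted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import yaml

from .records import BindingRecord, PEPTIDE_MAX_LEN

logger = logging.getLogger("capsmhc")

DIALECTS = ("iedb_benchmark", "anthem", "internal")


@dataclass
class ReadReport:
    n_read: int = 0
    n_valid: int = 0
    n_too_long: int = 0
    errors: List[Tuple[int, str]] = field(default_factory=list)  # (line number, message)


class EmptyDatasetError(ValueError):
    pass


def _parse_row(parts: List[str], dialect: str) -> BindingRecord:
    if dialect == "iedb_benchmark":
        if len(parts) < 7:
            raise ValueError(f"expected 7 columns, got {len(parts)}")
        _, _, allele, plen, kind, peptide, value = parts[:7]
        if int(plen) != len(peptide):
            raise ValueError(
                f"stated peptide_length {plen} != actual {len(peptide)}"
            )
        return BindingRecord(peptide, allele, kind, float(value))
    if dialect == "anthem":
        if len(parts) < 3:
            raise ValueError(f"expected 3 columns, got {len(parts)}")
        allele, peptide, label = parts[:3]
        return BindingRecord(peptide, allele, "binary", float(int(label)))
    if dialect == "internal":
        if len(parts) < 4:
            raise ValueError(f"expected 4 columns, got {len(parts)}")
        allele, peptide, kind, value = parts[:4]
        return BindingRecord(peptide, allele, kind, float(value))
    raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")


_HEADERS = {
    "iedb_benchmark": "date\treference\tallele\tpeptide_length\tmeasurement_kind\tpeptide\tvalue",
    "anthem": "allele\tpeptide\tlabel",
    "internal": "allele\tpeptide\tmeasurement_kind\tvalue",
}


def read_dataset(
    path, dialect: str = "internal", return_report: bool = False
):
    """Read a benchmark table into validated records.

    Raises :class:`EmptyDatasetError` when no valid rows remain; with
    ``return_report=True`` also returns the :class:`ReadReport` of skipped
    and malformed rows.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
    report = ReadReport()
    records: List[BindingRecord] = []
    header = _HEADERS[dialect].split("\t")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.strip().lower() for p in parts[: len(header)]] == header:
                continue
            report.n_read += 1
            try:
                if dialect == "iedb_benchmark":
                    pep = parts[5] if len(parts) > 5 else ""
                elif dialect == "anthem":
                    pep = parts[1] if len(parts) > 1 else ""
                else:
                    pep = parts[1] if len(parts) > 1 else ""
                if len(pep) > PEPTIDE_MAX_LEN:
                    report.n_too_long += 1
                    continue
                records.append(_parse_row(parts, dialect))
                report.n_valid += 1
            except (ValueError, IndexError) as e:
                report.errors.append((lineno, str(e)))
    if report.n_too_long:
        logger.info(
            "%s: skipped %d peptides longer than %d residues",
            path, report.n_too_long, PEPTIDE_MAX_LEN,
        )
    for lineno, msg in report.errors:
        logger.warning("%s:%d: %s", path, lineno, msg)
    if not records:
        raise EmptyDatasetError(f"no valid rows in {path} under dialect {dialect!r}")
    return (records, report) if return_report else records


def write_dataset(records: Sequence[BindingRecord], path, dialect: str = "internal") -> None:
    with open(path, "w") as fh:
        fh.write(_HEADERS[dialect] + "\n")
        for r in records:
            if dialect == "iedb_benchmark":
                fh.write(
                    f"-\t-\t{r.allele}\t{len(r.peptide)}\t{r.measurement_kind}"
                    f"\t{r.peptide}\t{r.value!r}\n"
                )
            elif dialect == "anthem":
                if r.measurement_kind != "binary":
                    raise ValueError("anthem dialect holds binary labels only")
                fh.write(f"{r.allele}\t{r.peptide}\t{int(r.value)}\n")
            else:
                fh.write(
                    f"{r.allele}\t{r.peptide}\t{r.measurement_kind}\t{r.value!r}\n"
                )


def write_allele_fasta(entries: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sorted(entries.items()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: model, training and importance
    settings plus the global seed and output directory."""

    encoding: str = "blosum62"
    fusion: str = "capsule"
    routing: bool = True
    routing_iters: int = 3
    n_capsules: int = 16
    capsule_dim: int = 16
    hidden_layers: List[int] = field(default_factory=lambda: [128, 64, 32])
    activation: str = "sigmoid"
    loss: str = "auto"
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 100
    n_repeats: int = 10
    seed: int = 0
    output_dir: str = "."

    def estimator_params(self) -> Dict[str, object]:
        return {
            "encoding": self.encoding,
            "fusion": self.fusion,
            "routing": self.routing,
            "routing_iters": self.routing_iters,
            "n_capsules": self.n_capsules,
            "capsule_dim": self.capsule_dim,
            "hidden_layers": tuple(self.hidden_layers),
            "activation": self.activation,
            "loss": self.loss,
            "lr": self.lr,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:12]
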