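"""Data model and I/O for longitudinal lesion cohorts.

The central record is one measurement of one genetic lesion in one patient
sample: a mutant-allele frequency from deep sequencing (``NGS``) or a
fraction of abnormal nuclei from FISH, together with the FACS tumor-cell
fraction of the sample.  Time is stored in months since the patient's first
sample.  A :class:`CohortTable` is a validated collection of such records;
a :class:`CrossSectionalMatrix` is a binary patients-by-lesions presence
matrix used for co-occurrence analysis.

The module also provides a fixture generator that converts simulated
presence trajectories into realistic raw observations, and graph
serialization (GraphML / DOT / TSV edge list) for the ordering networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ASSAYS = ("NGS", "FISH")

COHORT_COLUMNS = [
    "patient_id",
    "sample_time",
    "lesion_id",
    "assay",
    "raw_value",
    "facs_fraction",
    "treatment",
]


class CohortFormatError(ValueError):
    """Malformed cohort file (missing columns, unreadable table)."""


class CohortValidationError(ValueError):
    """Well-formed file whose rows violate a measurement invariant."""


@dataclass(frozen=True)
class LesionMeasurement:
    """One assay measurement of one lesion in one sample.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    sample_time : float
        Months since the patient's first sample (>= 0).
    lesion_id : str
        Free-form lesion label; gene-level vs variant-level analyses are
        obtained purely by the caller's choice of granularity.
    assay : {"NGS", "FISH"}
        ``NGS``: raw_value is a mutant-allele frequency in [0, 1].
        ``FISH``: raw_value is the fraction of abnormal nuclei in [0, 1].
    raw_value : float
        The raw measurement, in [0, 1].
    facs_fraction : float
        CD19+CD5+ tumor-cell fraction of the sample, in (0, 1].
    treatment_before_sample : str or None
        Therapy administered between the previous sample and this one,
        if any.
    """

    patient_id: str
    sample_time: float
    lesion_id: str
    assay: str
    raw_value: float
    facs_fraction: float = 1.0
    treatment_before_sample: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise CohortValidationError(
                f"assay must be one of {VALID_ASSAYS}, got {self.assay!r}"
            )
        if not 0.0 <= self.raw_value <= 1.0:
            raise CohortValidationError(
                f"raw_value must be in [0, 1], got {self.raw_value}"
            )
        if not 0.0 < self.facs_fraction <= 1.0:
            raise CohortValidationError(
                f"facs_fraction must be in (0, 1], got {self.facs_fraction}"
            )
        if self.sample_time < 0:
            raise CohortValidationError(
                f"sample_time must be >= 0, got {self.sample_time}"
            )


@dataclass
class CohortTable:
    """A validated longitudinal cohort.

    Measurement keys ``(patient_id, sample_time, lesion_id, assay)`` are
    unique.  Patients with fewer than two distinct sample times are kept
    but flagged with a warning: they cannot contribute ordering
    information.
    """

    measurements: list[LesionMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for i, m in enumerate(self.measurements):
            key = (m.patient_id, m.sample_time, m.lesion_id, m.assay)
            if key in seen:
                raise CohortValidationError(
                    f"duplicate measurement {key} (record {i})"
                )
            seen.add(key)
        for pid in self.single_timepoint_patients():
            logger.warning(
                "patient %s has <2 distinct sample times; it contributes "
                "no ordering information", pid,
            )

    @property
    def patients(self) -> list[str]:
        return sorted({m.patient_id for m in self.measurements})

    @property
    def lesions(self) -> list[str]:
        return sorted({m.lesion_id for m in self.measurements})

    def sample_times(self, patient_id: str) -> list[float]:
        return sorted({
            m.sample_time for m in self.measurements
            if m.patient_id == patient_id
        })

    def patient_sample(self, patient_id: str, sample_time: float
                       ) -> list[LesionMeasurement]:
        return [
            m for m in self.measurements
            if m.patient_id == patient_id and m.sample_time == sample_time
        ]

    def single_timepoint_patients(self) -> list[str]:
        return [p for p in self.patients if len(self.sample_times(p)) < 2]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": m.patient_id,
                "sample_time": m.sample_time,
                "lesion_id": m.lesion_id,
                "assay": m.assay,
                "raw_value": m.raw_value,
                "facs_fraction": m.facs_fraction,
                "treatment": m.treatment_before_sample or "",
            }
            for m in self.measurements
        ]
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return sorted(self.measurements, key=_mkey) == sorted(
            other.measurements, key=_mkey)


def _mkey(m: LesionMeasurement) -> tuple:
    return (m.patient_id, m.sample_time, m.lesion_id, m.assay)


@dataclass
class CrossSectionalMatrix:
    """Binary patients-by-lesions presence matrix (NaN = missing).

    ``matrix`` is a DataFrame indexed by patient_id with one column per
    lesion; entries are 0.0, 1.0 or NaN.
    """

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy(dtype=float)
        bad = ~(pd.isna(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            r, c = [x[0] for x in bad.nonzero()]
            raise CohortValidationError(
                f"non-binary entry {vals[r, c]!r} at patient "
                f"{self.matrix.index[r]!r}, lesion {self.matrix.columns[c]!r}"
            )

    @property
    def lesion_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.matrix.index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep(fmt: str) -> str:
    fmt = fmt.upper()
    if fmt == "TSV":
        return "\t"
    if fmt == "CSV":
        return ","
    raise ValueError(f"unknown tabular format {fmt!r}; use TSV or CSV")


def read_cohort(path: str | Path, format: str = "TSV") -> CohortTable:
    """Read a longitudinal cohort table.

    Expected columns: patient_id, sample_time, lesion_id, assay,
    raw_value, facs_fraction, treatment.  Empty or "." entries are
    missing; a missing facs_fraction defaults to 1.0 (sample treated as
    pure) with a warning.  Rows violating invariants are reported with
    their 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(format), dtype=str,
                     keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns
               and c != "treatment"]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s) {missing}")
    measurements = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        facs = rec.get("facs_fraction", "")
        if facs in ("", "."):
            logger.warning(
                "%s row %d: missing facs_fraction, assuming pure sample "
                "(1.0)", path, i)
            facs = "1.0"
        treat = rec.get("treatment", "")
        try:
            m = LesionMeasurement(
                patient_id=str(rec["patient_id"]),
                sample_time=float(rec["sample_time"]),
                lesion_id=str(rec["lesion_id"]),
                assay=str(rec["assay"]),
                raw_value=float(rec["raw_value"]),
                facs_fraction=float(facs),
                treatment_before_sample=None if treat in ("", ".")
                else str(treat),
            )
        except (CohortValidationError, ValueError) as exc:
            raise CohortValidationError(f"{path} row {i}: {exc}") from exc
        measurements.append(m)
    return CohortTable(measurements)


def write_cohort(cohort: CohortTable, path: str | Path,
                 format: str = "TSV") -> None:
    """Write a cohort table as TSV/CSV (round-trips with read_cohort)."""
    cohort.to_frame().to_csv(path, sep=_sep(format), index=False)


def read_crosssection(path: str | Path, format: str = "TSV"
                      ) -> CrossSectionalMatrix:
    """Read a binary patients-by-lesions matrix.

    First column = patient_id; remaining columns = lesion ids; entries
    0/1, with "." or empty meaning missing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(format), index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"{path}: no records") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise CohortFormatError(f"{path}: no records")
    df = df.replace({"": None, ".": None})
    try:
        mat = df.astype(float)
    except ValueError as exc:
        raise CohortValidationError(f"{path}: {exc}") from exc
    return CrossSectionalMatrix(mat)


def write_crosssection(m: CrossSectionalMatrix, path: str | Path,
                       format: str = "TSV") -> None:
    out = m.matrix.map(lambda v: "." if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep=_sep(format), index_label="patient_id")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def generate_fixture_cohort(n_patients: int, model, noise_sd: float = 0.0,
                            seed: int = 0,
                            fish_lesions: Iterable[str] = ("x2", "x4"),
                            ) -> CohortTable:
    """Simulate a cohort and convert it into raw observations.

    Presence trajectories are drawn from the Markov simulator; a lesion's
    true mutation cell frequency is 0.5 at its first positive sample
    (a newly expanding subclone) and 1.0 afterwards (fully clonal).
    NGS lesions report a mutant-allele frequency of 0.5 * MCF
    (heterozygous diploid convention), FISH lesions report the MCF
    directly; Gaussian noise with SD ``noise_sd`` is added and the result
    truncated to [0, 1].  Absent lesions report near-zero values.
    FACS purity is 1.0 throughout.  Deterministic in (args, seed).
    """
    import numpy as np

    from tedg.evosim import simulate_cohort

    fish = set(fish_lesions)
    cohort = simulate_cohort(model, n_patients, seed)
    rng = np.random.default_rng([seed, 987654321])
    measurements = []
    for patient in cohort.patients:
        pid = patient.patient_id
        first_seen: dict[str, float] = {}
        for t, _state, presence in patient.trajectory:
            for lesion, present in presence.items():
                if present and lesion not in first_seen:
                    first_seen[lesion] = t
                true_mcf = 0.0
                if present:
                    true_mcf = 0.5 if first_seen[lesion] == t else 1.0
                assay = "FISH" if lesion in fish else "NGS"
                center = true_mcf if assay == "FISH" else 0.5 * true_mcf
                value = center
                if noise_sd > 0:
                    value = float(
                        np.clip(center + rng.normal(0.0, noise_sd), 0.0, 1.0))
                measurements.append(LesionMeasurement(
                    patient_id=pid,
                    sample_time=float(t),
                    lesion_id=lesion,
                    assay=assay,
                    raw_value=value,
                    facs_fraction=1.0,
                ))
    return CohortTable(measurements)


# ---------------------------------------------------------------------------
# Graph serialization
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("graphml", "dot", "tsv")


def write_graph(graph: nx.DiGraph, path: str | Path,
                format: Literal["graphml", "dot", "tsv"] = "graphml"
                ) -> None:
    """Serialize an ordering graph.

    GraphML and TSV round-trip through :func:`read_graph`; DOT is a
    write-only export for layout tools.  Edge attribute "weight" and node
    attributes "recurrence"/"role" are preserved.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        g = _stringify_patients(graph)
        nx.write_graphml(g, path)
    elif fmt == "dot":
        _write_dot(graph, path)
    elif fmt == "tsv":
        rows = []
        for u, v, d in sorted(graph.edges(data=True)):
            rows.append({
                "source": u, "target": v,
                "weight": d.get("weight", 1.0),
                "supporting_patients": ",".join(
                    sorted(d.get("patients", ()))),
            })
        pd.DataFrame(
            rows, columns=["source", "target", "weight",
                           "supporting_patients"],
        ).to_csv(path, sep="\t", index=False)
        with open(path, "a") as fh:
            for n, d in sorted(graph.nodes(data=True)):
                fh.write(f"#node\t{n}\t{d.get('recurrence', 0)}\t"
                         f"{d.get('role', '')}\n")
    else:
        raise ValueError(
            f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}")


def read_graph(path: str | Path,
               format: Literal["graphml", "tsv"] = "graphml") -> nx.DiGraph:
    """Read a graph written by :func:`write_graph` (GraphML or TSV)."""
    from tedg.evograph import OrderGraph

    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        g = OrderGraph(role=raw.graph.get("role", ""))
        for n, d in raw.nodes(data=True):
            g.add_node(n, **{k: v for k, v in d.items()})
        for u, v, d in raw.edges(data=True):
            attrs = dict(d)
            pats = attrs.pop("patients", "")
            g.add_edge(u, v, **attrs)
            if pats:
                g[u][v]["patients"] = frozenset(pats.split(","))
        return g
    if fmt == "tsv":
        g = OrderGraph(role="")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#node":
                    _, n, rec, role = parts
                    g.add_node(n, recurrence=int(rec))
                    if role:
                        g.nodes[n]["role"] = role
                    continue
                rec = dict(zip(header, parts))
                g.add_edge(rec["source"], rec["target"],
                           weight=float(rec["weight"]))
                if rec.get("supporting_patients"):
                    g[rec["source"]][rec["target"]]["patients"] = frozenset(
                        rec["supporting_patients"].split(","))
        return g
    raise ValueError(f"cannot read graph format {format!r}")


def _stringify_patients(graph: nx.DiGraph) -> nx.DiGraph:
    g = graph.copy()
    for _u, _v, d in g.edges(data=True):
        if "patients" in d:
            d["patients"] = ",".join(sorted(d["patients"]))
    return g


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    # Plain DOT emitter: node/edge attributes quoted, deterministic order.
    def q(s) -> str:
        return '"' + str(s).replace('"', r'\"') + '"'

    with open(path, "w") as fh:
        fh.write("digraph TEDG {\n")
        for n, d in sorted(graph.nodes(data=True)):
            attrs = [f"recurrence={d['recurrence']}"] \
                if "recurrence" in d else []
            if "role" in d:
                attrs.append(f"role={q(d['role'])}")
            fh.write(f"  {q(n)}" +
                     (f" [{', '.join(attrs)}]" if attrs else "") + ";\n")
        for u, v, d in sorted(graph.edges(data=True)):
            w = d.get("weight", 1.0)
            label = f"{w:.4g}" if isinstance(w, float) else str(w)
            fh.write(f"  {q(u)} -> {q(v)} [weight={label}];\n")
        fh.write("}\n")
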