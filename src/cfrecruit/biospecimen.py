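"""Sputum processing workflow validation: timing, labeling, shipping, QC.

The processing protocol: sputum is collected into a conical tube (at most
20 minutes of collection), transported on ice, and laboratory processing
must begin within one hour of the start of collection, with up to three
further hours to complete processing.  Centrifugation (20 min, 2800 g,
4 degC) separates a lipid layer (fraction L), an aqueous layer split into
a buffer-diluted half (SA) and a protease-inhibitor-diluted half (SB), and
a cell pellet (P).  Aliquots are labeled with participant ID, collection
date, fraction identifier, sample number and aliquot number, frozen at
-70 degC, and shipped on dry ice in split batches so that the loss of any
single shipment cannot destroy every aliquot of a sample.

Cytology QC flags oral contamination (>= 5 squamous epithelial cells per
low-power field) and low counting adequacy (fewer than 200 cells counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable

__all__ = [
    "FRACTIONS",
    "DEFAULT_FRACTION_PLAN",
    "SampleRecord",
    "Aliquot",
    "QCResult",
    "validate_timing",
    "make_labels",
    "render_label",
    "parse_label",
    "assign_split_batches",
    "qc_sample",
]

FRACTIONS = ("L", "SA", "SB", "P")
#: lipid, two aqueous-with-buffer, two aqueous-with-protease-inhibitor, pellet
DEFAULT_FRACTION_PLAN: dict[str, int] = {"L": 1, "SA": 2, "SB": 2, "P": 1}

COLLECTION_LIMIT_MIN = 20
INITIATION_LIMIT_MIN = 60
PROCESSING_LIMIT_MIN = 180
SQUAMOUS_CONTAMINATION_THRESHOLD = 5
ADEQUATE_CELL_COUNT = 200


@dataclass
class SampleRecord:
    """One timed sputum sample from collection through processing."""

    sample_id: str
    participant_id: str
    collection_start: datetime
    collection_end: datetime
    transport_start: datetime
    processing_start: datetime
    processing_end: datetime
    sputum_weight_g: float | None = None
    context: str = "enrollment"
    sample_number: int = 1

    def ordered_timestamps(self) -> list[datetime]:
        return [
            self.collection_start,
            self.collection_end,
            self.transport_start,
            self.processing_start,
            self.processing_end,
        ]


def validate_timing(sample: SampleRecord) -> list[str]:
    """Protocol timing violations for one sample (empty list = compliant).

    Checks: collection longer than 20 minutes; more than one hour from the
    start of collection to the initiation of processing; more than three
    hours from initiation to completion of processing.  Out-of-order
    timestamps raise rather than flag, since no interval is then defined.
    """
    ts = sample.ordered_timestamps()
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"timestamps out of order for sample {sample.sample_id}")
    violations = []
    minutes = lambda a, b: (b - a).total_seconds() / 60.0
    if minutes(sample.collection_start, sample.collection_end) > COLLECTION_LIMIT_MIN:
        violations.append(f"collection > {COLLECTION_LIMIT_MIN} min")
    if minutes(sample.collection_start, sample.processing_start) > INITIATION_LIMIT_MIN:
        violations.append("processing initiation > 1 h after collection start")
    if minutes(sample.processing_start, sample.processing_end) > PROCESSING_LIMIT_MIN:
        violations.append("processing > 3 h")
    return violations


@dataclass(frozen=True)
class Aliquot:
    """One labeled cryovial of one fraction of one sample."""

    participant_id: str
    collection_date: datetime
    fraction: str
    sample_number: int
    aliquot_number: int
    diluted_with_buffer: bool = False       # SA: 1:1 HBSS
    protease_inhibitor: bool = False        # SB: 1:1 protease inhibitor cocktail
    storage_temperature_C: float = -70.0
    shipment_id: str | None = None

    @property
    def label(self) -> str:
        return render_label(self)


def render_label(a: Aliquot) -> str:
    """`<ID>_<YYYYMMDD>_<FRACTION>_<sample#>_<aliquot#>`."""
    return (
        f"{a.participant_id}_{a.collection_date:%Y%m%d}_"
        f"{a.fraction}_{a.sample_number}_{a.aliquot_number}"
    )


def parse_label(label: str) -> Aliquot:
    """Inverse of :func:`render_label` (dilution flags restored per fraction)."""
    parts = label.rsplit("_", 4)
    if len(parts) != 5:
        raise ValueError(f"unparseable label: {label!r}")
    pid, datestr, fraction, s_num, a_num = parts
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r} in label {label!r}")
    return Aliquot(
        participant_id=pid,
        collection_date=datetime.strptime(datestr, "%Y%m%d"),
        fraction=fraction,
        sample_number=int(s_num),
        aliquot_number=int(a_num),
        diluted_with_buffer=fraction == "SA",
        protease_inhibitor=fraction == "SB",
    )


def make_labels(
    sample: SampleRecord,
    fraction_plan: dict[str, int] | None = None,
) -> list[Aliquot]:
    """Generate labeled aliquots for a processed sample.

    Default plan: one lipid (L), two buffer-diluted aqueous (SA), two
    protease-inhibitor aqueous (SB), one pellet (P).  Aliquot numbers run
    1..n within each fraction; labels are unique and deterministic.
    """
    if fraction_plan is None:
        fraction_plan = dict(DEFAULT_FRACTION_PLAN)
    if not fraction_plan:
        raise ValueError("fraction plan is empty")
    unknown = set(fraction_plan) - set(FRACTIONS)
    if unknown:
        raise ValueError(f"unknown fraction(s): {sorted(unknown)}")
    if any(n < 1 for n in fraction_plan.values()):
        raise ValueError("aliquot counts must be >= 1")
    aliquots = []
    for fraction in FRACTIONS:
        for i in range(fraction_plan.get(fraction, 0)):
            aliquots.append(
                Aliquot(
                    participant_id=sample.participant_id,
                    collection_date=datetime(
                        sample.collection_start.year,
                        sample.collection_start.month,
                        sample.collection_start.day,
                    ),
                    fraction=fraction,
                    sample_number=sample.sample_number,
                    aliquot_number=i + 1,
                    diluted_with_buffer=fraction == "SA",
                    protease_inhibitor=fraction == "SB",
                )
            )
    return aliquots


@dataclass
class SplitBatchResult:
    """Shipment assignment with per-sample split verification."""

    assignments: dict[str, str]          # label -> shipment_id
    shipment_sizes: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def shipments_of(self, labels: Iterable[str]) -> set[str]:
        return {self.assignments[l] for l in labels}


def assign_split_batches(aliquots: list[Aliquot], n_shipments: int = 2) -> SplitBatchResult:
    """Distribute aliquots over shipments so no shipment holds a whole sample.

    For every sample with at least two aliquots, its aliquots span at
    least two shipments, so the loss of any single shipment leaves
    material.  Shipment sizes are kept balanced by always filling the
    currently smallest shipments first.  A sample with a single aliquot
    cannot be protected and is flagged with a warning, not an error.
    """
    if n_shipments < 2:
        raise ValueError("split-batch shipping needs n_shipments >= 2")
    shipment_ids = [f"S{i + 1}" for i in range(n_shipments)]
    sizes = {sid: 0 for sid in shipment_ids}
    assignments: dict[str, str] = {}
    warnings: list[str] = []
    by_sample: dict[tuple[str, int], list[Aliquot]] = {}
    for a in aliquots:
        by_sample.setdefault((a.participant_id, a.sample_number), []).append(a)
    for key in sorted(by_sample):
        group = sorted(by_sample[key], key=lambda a: (a.fraction, a.aliquot_number))
        if len(group) == 1:
            warnings.append(
                f"sample {key[0]}#{key[1]} has a single aliquot; cannot split across shipments"
            )
        # Fill smallest shipments first, cycling so the group spans
        # min(len(group), n_shipments) distinct shipments.
        order = sorted(shipment_ids, key=lambda s: (sizes[s], s))
        for i, a in enumerate(group):
            sid = order[i % len(order)]
            assignments[a.label] = sid
            sizes[sid] += 1
    return SplitBatchResult(assignments=assignments, shipment_sizes=sizes, warnings=warnings)


@dataclass(frozen=True)
class QCResult:
    squamous_cells_per_lpf: int
    oral_contamination: bool
    cells_counted: int
    count_adequacy: str  # adequate | low
    differential: dict[str, float]


def qc_sample(
    squamous_per_lpf: int,
    cells_counted: int,
    differential: dict[str, float],
    tol: float = 1e-9,
) -> QCResult:
    """Cytology QC for one sample.

    Oral contamination iff >= 5 squamous epithelial cells per low-power
    field; counting adequacy is "low" below 200 cells; the differential
    (cell-type fractions) must sum to 1 within tolerance.
    """
    if squamous_per_lpf < 0 or cells_counted < 0:
        raise ValueError("counts must be non-negative")
    if any(not 0.0 <= f <= 1.0 for f in differential.values()):
        raise ValueError("differential fractions must lie in [0, 1]")
    total = sum(differential.values())
    if abs(total - 1.0) > max(tol, 1e-9):
        raise ValueError(f"differential fractions sum to {total}, not 1")
    return QCResult(
        squamous_cells_per_lpf=squamous_per_lpf,
        oral_contamination=squamous_per_lpf >= SQUAMOUS_CONTAMINATION_THRESHOLD,
        cells_counted=cells_counted,
        count_adequacy="adequate" if cells_counted >= ADEQUATE_CELL_COUNT else "low",
        differential=dict(differential),
    )
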