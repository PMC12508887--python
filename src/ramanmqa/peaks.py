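"""Curated metabolite band library, peak assignment, and cluster annotation.

The shipped table collects the band positions used for bacteriocyte analysis
(deoxyribose, nucleic-acid PO2-, triglycerides, palmitoleic acid, cholesterol,
phenylalanine, lanosterol, squalene, glycogen, NADH, glucose, tryptophan and
the threonine internal standard) together with a fixation-artifact exclusion
window around 980 cm^-1: methanol fixation perturbs that band, so peaks
falling inside it are never assigned.

Assignments are tentative throughout — vibrational bands are rarely unique to
one molecule — so :func:`assign_peak` returns distance-ranked candidates, not
a single identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .core import PeakWindow
from .errors import ConfigError

__all__ = [
    "LibraryEntry",
    "PeakLibrary",
    "PeakAssignment",
    "ClusterAnnotation",
    "default_library",
    "assign_peak",
    "annotate_clusters",
]

#: Compartment class of each library band center, used by annotate_clusters.
CLASS_BY_CENTER: dict[float, str] = {
    1078.0: "nucleus",
    1423.0: "nucleus",
    1746.0: "lipid_droplet",
    1263.0: "lipid_droplet",
    1656.0: "lipid_droplet",
    3009.0: "lipid_droplet",
    1083.0: "lipid_droplet",
    930.0: "symbiont",
    943.0: "symbiont",
    1643.0: "symbiont",
    1379.0: "symbiont",
    1666.0: "symbiont",
    484.0: "symbiont",
    1006.0: "cytoplasm",
}


@dataclass(frozen=True)
class LibraryEntry:
    """One metabolite: its band windows plus a free-text assignment note."""

    name: str
    windows: tuple[PeakWindow, ...]
    note: str = ""


@dataclass
class PeakLibrary:
    """Metabolite band table with fixation-artifact exclusion windows."""

    entries: dict[str, LibraryEntry]
    exclusions: list[PeakWindow] = field(default_factory=list)
    match_tolerance: float = 8.0

    def __post_init__(self) -> None:
        if self.match_tolerance <= 0:
            raise ConfigError("match_tolerance must be positive")
        for entry in self.entries.values():
            if not entry.windows:
                raise ConfigError(f"library entry {entry.name!r} has no windows")
            for w in entry.windows:
                for ex in self.exclusions:
                    if w.overlaps(ex):
                        raise ConfigError(
                            f"entry window {entry.name} @ {w.center} overlaps "
                            f"exclusion window @ {ex.center}"
                        )

    def __getitem__(self, name: str) -> LibraryEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> Path:
        doc = {
            "match_tolerance": self.match_tolerance,
            "metabolites": [
                {
                    "metabolite": e.name,
                    "windows": [
                        {"center": w.center, "half_width": w.half_width} for w in e.windows
                    ],
                    "note": e.note,
                }
                for e in self.entries.values()
            ],
            "exclusions": [
                {"center": w.center, "half_width": w.half_width} for w in self.exclusions
            ],
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PeakLibrary":
        doc = yaml.safe_load(Path(path).read_text())
        entries = {}
        for item in doc.get("metabolites", []):
            name = item["metabolite"]
            windows = tuple(
                PeakWindow(float(w["center"]), float(w.get("half_width", 8.0)), name)
                for w in item["windows"]
            )
            entries[name] = LibraryEntry(name, windows, item.get("note", ""))
        exclusions = [
            PeakWindow(float(w["center"]), float(w.get("half_width", 8.0)), "excluded")
            for w in doc.get("exclusions", [])
        ]
        return cls(entries, exclusions, float(doc.get("match_tolerance", 8.0)))


def _entry(name: str, centers: Sequence[float], note: str) -> LibraryEntry:
    return LibraryEntry(
        name, tuple(PeakWindow(float(c), 8.0, name) for c in centers), note
    )


def default_library() -> PeakLibrary:
    """The shipped bacteriocyte band table (all assignments tentative)."""
    entries = [
        _entry("deoxyribose", [1423], "tentatively assigned; deoxyribose (DNA)"),
        _entry("nucleic_acid_po2", [1078], "tentatively assigned; PO2- stretching (nucleic acids)"),
        _entry("triglyceride", [1746], "tentatively assigned; C=O vibration (triglycerides)"),
        _entry("palmitoleic_acid", [1263, 1656, 3009], "tentatively assigned; palmitoleic acid"),
        _entry("cholesterol", [1083], "tentatively assigned; cholesterol"),
        _entry("phenylalanine", [1006], "tentatively assigned; phenylalanine ring breathing"),
        _entry("lanosterol", [930, 943, 1643], "tentatively assigned; lanosterol"),
        _entry("squalene", [1379, 1666], "tentatively assigned; squalene"),
        _entry("glycogen", [484], "tentatively assigned; glycogen"),
        _entry("nadh", [1114], "tentatively assigned; NADH"),
        _entry("glucose", [1127], "tentatively assigned; glucose"),
        _entry("tryptophan", [1557], "tentatively assigned; tryptophan"),
        _entry("threonine", [1341], "tentatively assigned; threonine (internal standard)"),
    ]
    exclusions = [PeakWindow(980.0, 8.0, "fixation_artifact")]
    return PeakLibrary({e.name: e for e in entries}, exclusions)


@dataclass(frozen=True)
class PeakAssignment:
    """Candidate assignments for one observed peak position."""

    position: float
    excluded: bool
    candidates: tuple[tuple[str, float, float], ...]  # (metabolite, center, distance)


def assign_peak(
    position: float, library: PeakLibrary, tolerance: Optional[float] = None
) -> PeakAssignment:
    """Rank library bands within ``tolerance`` cm^-1 of ``position``.

    Positions falling inside a fixation-artifact exclusion window return
    ``excluded=True`` with no candidates.
    """
    tol = library.match_tolerance if tolerance is None else float(tolerance)
    if tol <= 0:
        raise ConfigError("tolerance must be positive")
    for ex in library.exclusions:
        if ex.lo <= position <= ex.hi:
            return PeakAssignment(position, True, ())
    hits = []
    for entry in library.entries.values():
        for w in entry.windows:
            dist = abs(w.center - position)
            if dist <= tol:
                hits.append((entry.name, w.center, dist))
    hits.sort(key=lambda h: (h[2], h[1]))
    return PeakAssignment(position, False, tuple(hits))


@dataclass(frozen=True)
class ClusterAnnotation:
    """Compartment class and band-level assignments for one cluster."""

    cluster: int
    compartment_class: str
    bands: tuple[tuple[float, float, PeakAssignment], ...]  # (position, prominence, assignment)


def annotate_clusters(candidates_per_cluster, library: PeakLibrary) -> list[ClusterAnnotation]:
    """Label clusters by the compartment class of their difference peaks.

    ``candidates_per_cluster`` is the output of
    :func:`ramanmqa.multivariate.difference_peaks`: per cluster, a
    prominence-ranked list of ``(position, prominence)`` bands.  Each band is
    assigned via :func:`assign_peak`; the cluster class is the majority class
    among assigned bands, with ties resolved by the class of the
    highest-prominence assigned band.  Clusters with no assignable band are
    labeled ``"unassigned"``.
    """
    out = []
    for i, bands in enumerate(candidates_per_cluster):
        annotated = []
        votes: dict[str, int] = {}
        first_class: Optional[str] = None
        for position, prominence in bands:
            assignment = assign_peak(position, library)
            annotated.append((float(position), float(prominence), assignment))
            if assignment.excluded or not assignment.candidates:
                continue
            name, center, _ = assignment.candidates[0]
            cls = CLASS_BY_CENTER.get(center, "unassigned")
            votes[cls] = votes.get(cls, 0) + 1
            if first_class is None:
                first_class = cls
        if not votes:
            label = "unassigned"
        else:
            best = max(votes.values())
            tied = [c for c, v in votes.items() if v == best]
            label = tied[0] if len(tied) == 1 else first_class  # type: ignore[assignment]
        out.append(ClusterAnnotation(i, label, tuple(annotated)))
    return out
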