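"""Order parameters for selecting the optimal subdivision.

Three complementary scores characterize each strain-minimizing partition:

* **integrity** — mean over coat proteins of the largest fraction of a
  protein's residues assigned to a single domain (1.0 when domains are
  unions of whole proteins); optionally evaluated over structural
  subdomains instead of whole proteins;
* **tile types** — number of structurally inequivalent domain classes, by
  single-linkage clustering of domain sizes with a tolerance relative to
  the mean size (capsomere tilings yield very few types);
* **interlocking** — the larger of the N- and C-terminal averages, over
  proteins, of terminal residues assigned to a domain other than the
  protein's dominant one (swapped arms across domains).

Viable basic mechanical units appear as integrity maxima with few tile
types; among ties the subdivision with the smallest units (largest Q) is
preferred.  The selection is advisory: the full profiles are retained in
the report for inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capsid_io import CapsidStructure
from .decomposition import Partition, StrainProfile
from .enm import ModeSpectrum
from .rigid_projection import build_rigid_basis, captured_fraction

logger = logging.getLogger("capsid_domains")

DEFAULT_TILE_TOLERANCE = 0.03
DEFAULT_TERMINAL_LENGTH = 20
DEFAULT_MAX_TILE_TYPES = 3


def integrity_score(partition, grouping: dict) -> float:
    """Unweighted mean over groups of the largest fraction of a group's
    residues assigned to a single domain.

    ``grouping`` maps a group key (protein id, or (protein, subdomain)
    pair) to a residue index array; in subdomain mode it may cover only a
    subset of residues.
    """
    labels = np.asarray(getattr(partition, "labels", partition), dtype=int)
    if not grouping:
        raise ValueError("empty grouping")
    scores = []
    for key, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        if len(idx) == 0:
            raise ValueError(f"group {key!r} is empty")
        counts = np.bincount(labels[idx])
        scores.append(counts.max() / len(idx))
    return float(np.mean(scores))


def tile_types(partition, tolerance: float = DEFAULT_TILE_TOLERANCE):
    """(number of types, domain -> type map) by single-linkage clustering of
    domain sizes; two domains share a type when connected by a chain of size
    differences each within ``tolerance`` times the mean domain size."""
    labels = np.asarray(getattr(partition, "labels", partition), dtype=int)
    sizes = np.bincount(labels)
    sizes = sizes[sizes > 0]
    uniq = np.unique(labels)
    size_of = {int(d): int(np.sum(labels == d)) for d in uniq}
    band = tolerance * sizes.mean()
    order = sorted(size_of, key=size_of.get)
    type_map = {}
    t = 0
    prev = None
    for d in order:
        if prev is not None and size_of[d] - size_of[prev] > band:
            t += 1
        type_map[d] = t
        prev = d
    return t + 1, type_map


def interlocking(
    partition,
    structure: CapsidStructure,
    terminal_length: int = DEFAULT_TERMINAL_LENGTH,
) -> float:
    """Average number of terminal residues assigned away from the protein's
    dominant domain; the larger of the N- and C-terminus averages.

    For proteins shorter than twice ``terminal_length`` the window is
    clipped to half the protein length (logged).
    """
    labels = np.asarray(getattr(partition, "labels", partition), dtype=int)
    n_count, c_count = [], []
    clipped = False
    for pid, idx in structure.proteins.items():
        t = terminal_length
        if len(idx) < 2 * t:
            t = len(idx) // 2
            clipped = True
        dominant = np.bincount(labels[idx]).argmax()
        n_count.append(int(np.sum(labels[idx[:t]] != dominant)))
        c_count.append(int(np.sum(labels[idx[len(idx) - t:]] != dominant)))
    if clipped:
        logger.info("terminal window clipped for proteins shorter than %d residues",
                    2 * terminal_length)
    return float(max(np.mean(n_count), np.mean(c_count)))


# ---------------------------------------------------------------------------
# report assembly and candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class DecompositionReport:
    """Per-Q profiles of all order parameters plus ranked optimal-Q
    candidates.  ``records`` columns: Q, total_strain, integrity,
    subdomain_integrity (NaN when no subdomains are defined), n_tile_types,
    interlocking, captured_fraction, seed, restarts."""

    records: pd.DataFrame
    partitions: dict[int, Partition]
    candidates: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "meta": self.meta,
            "records": self.records.to_dict(orient="records"),
            "candidates": self.candidates,
            "partitions": {
                str(q): p.labels.tolist() for q, p in self.partitions.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def build_report(
    profile: StrainProfile,
    spectrum: ModeSpectrum,
    structure: CapsidStructure,
    subdomains: dict | None = None,
    tile_tolerance: float = DEFAULT_TILE_TOLERANCE,
    terminal_length: int = DEFAULT_TERMINAL_LENGTH,
    max_tile_types: int = DEFAULT_MAX_TILE_TYPES,
    meta: dict | None = None,
) -> DecompositionReport:
    """Evaluate every order parameter for each swept Q and rank candidates."""
    grouping = structure.proteins
    rows = []
    for q in sorted(profile.partitions):
        part = profile.partitions[q]
        n_types, _ = tile_types(part, tile_tolerance)
        basis = build_rigid_basis(structure, part)
        rows.append(
            {
                "Q": q,
                "total_strain": part.total_strain,
                "integrity": integrity_score(part, grouping),
                "subdomain_integrity": (
                    integrity_score(part, subdomains) if subdomains else np.nan
                ),
                "n_tile_types": n_types,
                "interlocking": interlocking(part, structure, terminal_length),
                "captured_fraction": captured_fraction(spectrum, basis),
                "seed": part.seed,
                "restarts": part.restarts,
            }
        )
    report = DecompositionReport(
        records=pd.DataFrame(rows),
        partitions=dict(profile.partitions),
        meta=meta or {},
    )
    report.candidates = select_optimal(report, max_tile_types=max_tile_types)
    return report


def select_optimal(
    report: DecompositionReport, max_tile_types: int = DEFAULT_MAX_TILE_TYPES
) -> list[dict]:
    """Ranked candidate Q values: interior local maxima of the integrity
    profile whose tile-type count does not exceed ``max_tile_types``, sorted
    by integrity and then by larger Q (preferring the smallest viable
    units).  Advisory — the report keeps all profiles for human override."""
    rec = report.records.sort_values("Q").reset_index(drop=True)
    if len(rec) < 3:
        raise ValueError("need at least 3 swept Q values to rank candidates")
    integ = rec["integrity"].to_numpy()
    # plateau-aware interior local maxima: runs of equal value higher than
    # both neighboring runs
    runs = []
    start = 0
    for i in range(1, len(integ) + 1):
        if i == len(integ) or integ[i] != integ[start]:
            runs.append((start, i - 1))
            start = i
    candidates = []
    for ri, (a, b) in enumerate(runs):
        if ri == 0 or ri == len(runs) - 1:
            continue  # boundary runs are not interior peaks
        if integ[a] > integ[runs[ri - 1][1]] and integ[a] > integ[runs[ri + 1][0]]:
            for i in range(a, b + 1):
                candidates.append(rec.iloc[i])
    out = []
    for row in candidates:
        flags = []
        if row["n_tile_types"] > max_tile_types:
            flags.append(f"too many tile types ({int(row['n_tile_types'])})")
            continue
        if row["interlocking"] > 0:
            flags.append("interlocked termini")
        out.append(
            {
                "Q": int(row["Q"]),
                "integrity": float(row["integrity"]),
                "n_tile_types": int(row["n_tile_types"]),
                "interlocking": float(row["interlocking"]),
                "captured_fraction": float(row["captured_fraction"]),
                "flags": flags,
            }
        )
    out.sort(key=lambda c: (-c["integrity"], -c["Q"]))
    if not out:
        logger.warning("no interior integrity peak with <= %d tile types; "
                       "no optimal-Q candidates", max_tile_types)
    return out
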