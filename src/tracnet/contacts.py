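"""Residue-contact records and binary contact fingerprints.

Contact detection itself (distance/angle criteria) happens upstream; this
module only parses the upstream tool's tab-separated output and turns it
into frames x contacts 0/1 fingerprint matrices, the input representation
for everything downstream.
"""
from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ResidueID",
    "ContactRecord",
    "FingerprintMatrix",
    "ContactParseError",
    "FingerprintFormatError",
    "KNOWN_INTERACTION_TYPES",
    "read_getcontacts",
    "binarize",
    "write_fingerprint",
    "read_fingerprint",
    "pair_label",
    "parse_pair_label",
]

#: Interaction-type tokens emitted by the upstream contact detector:
#: salt bridge, hydrogen-bond variants, van der Waals, pi-stacking,
#: pi-cation, T-stacking and water-bridged variants.
KNOWN_INTERACTION_TYPES = frozenset(
    {
        "sb",
        "hb",
        "hbbb",
        "hbsb",
        "hbss",
        "hbbs",
        "hbls",
        "hblb",
        "vdw",
        "ps",
        "pc",
        "ts",
        "wb",
        "wb2",
        "lwb",
        "lwb2",
    }
)

_GENERIC_NUMBER_RE = re.compile(r"^(\d+\.\d+|\d+x\d+|[A-Z]+\d*)$")


class ContactParseError(ValueError):
    """Raised for malformed contact-record lines (carries the line number)."""


class FingerprintFormatError(ValueError):
    """Raised when a serialized fingerprint file is truncated or mis-versioned."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """One residue endpoint of a contact.

    ``generic_number`` is an optional cross-receptor label (e.g. the
    Ballesteros-Weinstein "3.50" or a loop label like "ECL2") and does not
    participate in equality-relevant ordering beyond its field position.
    """

    chain: str
    resname: str
    resid: int
    generic_number: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.resid <= 0:
            raise ValueError(f"resid must be a positive integer, got {self.resid}")
        if self.generic_number is not None and not _GENERIC_NUMBER_RE.match(
            self.generic_number
        ):
            raise ValueError(f"bad generic number {self.generic_number!r}")

    @property
    def sort_key(self) -> tuple[str, int]:
        return (self.chain, self.resid)

    def __str__(self) -> str:  # canonical "A:ARG:131" form
        return f"{self.chain}:{self.resname}:{self.resid}"


@dataclass(frozen=True)
class ContactRecord:
    """A single interaction observation at one frame."""

    frame: int
    kind: str
    residue_a: ResidueID
    residue_b: ResidueID

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if self.residue_a == self.residue_b:
            raise ValueError(f"self-contact at frame {self.frame}: {self.residue_a}")


def pair_label(a: ResidueID, b: ResidueID, kind: str | None = None) -> str:
    """Canonical column label for a residue pair.

    The endpoint with the smaller ``(chain, resid)`` comes first so that
    (a, b) and (b, a) observations land in the same column.  With ``kind``
    the label is type-qualified (used when interaction types are kept
    separate).
    """
    first, second = sorted((a, b), key=lambda r: r.sort_key)
    base = f"{first}_{second}"
    return f"{base}|{kind}" if kind is not None else base


_LABEL_RE = re.compile(
    r"^([^:]+):([^:]+):(\d+)_([^:]+):([^:]+):(\d+)(?:\|(\w+))?$"
)


def parse_pair_label(label: str) -> tuple[ResidueID, ResidueID, str | None]:
    """Invert :func:`pair_label`; raises ``ValueError`` on foreign labels."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unparsable contact label {label!r}")
    a = ResidueID(m.group(1), m.group(2), int(m.group(3)))
    b = ResidueID(m.group(4), m.group(5), int(m.group(6)))
    return a, b, m.group(7)


@dataclass
class FingerprintMatrix:
    """Frames x contacts binary matrix with canonical contact labels.

    ``values[f, c]`` is 1 iff contact ``contact_labels[c]`` is formed at
    frame ``f``.  Frames are 0-based.  ``frame_time_step`` is the optional
    physical time per frame in nanoseconds (presentation only; all analysis
    runs in frame units).
    """

    values: np.ndarray
    contact_labels: list[str]
    trajectory_id: str = ""
    frame_time_step: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D frames x contacts matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        self.contact_labels = list(self.contact_labels)
        if len(self.contact_labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if len(set(self.contact_labels)) != len(self.contact_labels):
            raise ValueError("contact labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.values.shape[1]

    def restrict(self, labels: Sequence[str], fill_missing: bool = False) -> "FingerprintMatrix":
        """Column-subset (and reorder) to ``labels``.

        With ``fill_missing`` labels absent from this matrix become all-zero
        columns (the union-mode convention); otherwise absence is an error.
        """
        index = {lab: i for i, lab in enumerate(self.contact_labels)}
        cols = np.zeros((self.n_frames, len(labels)), dtype=np.uint8)
        for j, lab in enumerate(labels):
            if lab in index:
                cols[:, j] = self.values[:, index[lab]]
            elif not fill_missing:
                raise KeyError(f"contact {lab!r} absent from trajectory {self.trajectory_id!r}")
        return FingerprintMatrix(
            cols, list(labels), self.trajectory_id, self.frame_time_step
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintMatrix):
            return NotImplemented
        return (
            self.contact_labels == other.contact_labels
            and self.trajectory_id == other.trajectory_id
            and np.array_equal(self.values, other.values)
        )


def _parse_atom_token(token: str, lineno: int) -> ResidueID:
    parts = token.split(":")
    if len(parts) < 3:
        raise ContactParseError(
            f"line {lineno}: atom token {token!r} needs chain:resname:resid[:atom]"
        )
    chain, resname, resid_s = parts[0], parts[1], parts[2]
    try:
        resid = int(resid_s)
    except ValueError:
        raise ContactParseError(
            f"line {lineno}: unparsable residue number {resid_s!r} in {token!r}"
        ) from None
    return ResidueID(chain, resname, resid)


def read_getcontacts(path) -> list[ContactRecord]:
    """Parse a tab-separated contact file into :class:`ContactRecord` objects.

    Lines starting with ``#`` are comments.  Each data line carries at least
    ``frame  type  atom_a  atom_b`` where atoms are ``CHAIN:RESNAME:RESID:ATOM``
    tokens (the atom name is dropped: analysis is residue-pair grained).
    Unknown interaction-type tokens are kept with kind ``"other"`` and a
    warning; structurally malformed lines raise :class:`ContactParseError`.
    """
    records: list[ContactRecord] = []
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ContactParseError(
                    f"line {lineno}: expected >=4 tab-separated fields, got {len(fields)}"
                )
            try:
                frame = int(fields[0])
            except ValueError:
                raise ContactParseError(
                    f"line {lineno}: unparsable frame index {fields[0]!r}"
                ) from None
            kind = fields[1]
            if kind not in KNOWN_INTERACTION_TYPES:
                warnings.warn(
                    f"line {lineno}: unknown interaction type {kind!r}; keeping as 'other'",
                    stacklevel=2,
                )
                kind = "other"
            a = _parse_atom_token(fields[2], lineno)
            b = _parse_atom_token(fields[3], lineno)
            if frame < 0:
                raise ContactParseError(f"line {lineno}: negative frame {frame}")
            if a == b:
                # same residue via two atoms: not a pair contact
                continue
            records.append(ContactRecord(frame, kind, a, b))
    return records


#: water-bridged interaction tokens (one or two bridging waters)
WATER_BRIDGED_TYPES = frozenset({"wb", "wb2", "lwb", "lwb2"})


def binarize(
    records: Iterable[ContactRecord],
    n_frames: int,
    collapse_types: bool = True,
    trajectory_id: str = "",
    include_water_bridged: bool = True,
) -> FingerprintMatrix:
    """Turn contact records into a frames x contacts 0/1 matrix.

    With ``collapse_types`` (default) every interaction type between the same
    residue pair maps to one column; an entry is 1 iff any record for that
    pair exists at that frame.  Columns are ordered lexicographically by
    label and only observed pairs get columns.  Water-bridged records are
    ordinary protein-protein pair contacts by default; set
    ``include_water_bridged=False`` to drop them.
    """
    cells: set[tuple[int, str]] = set()
    for rec in records:
        if not include_water_bridged and rec.kind in WATER_BRIDGED_TYPES:
            continue
        if rec.frame >= n_frames:
            raise ValueError(
                f"record frame {rec.frame} out of range for n_frames={n_frames}"
            )
        label = pair_label(
            rec.residue_a, rec.residue_b, None if collapse_types else rec.kind
        )
        cells.add((rec.frame, label))
    labels = sorted({lab for _, lab in cells})
    col = {lab: j for j, lab in enumerate(labels)}
    values = np.zeros((n_frames, len(labels)), dtype=np.uint8)
    for frame, lab in cells:
        values[frame, col[lab]] = 1
    return FingerprintMatrix(values, labels, trajectory_id)


_FORMAT_TAG = "tracnet-fingerprint v1"


def write_fingerprint(matrix: FingerprintMatrix, path) -> None:
    """Serialize a fingerprint as self-describing plain text.

    Layout: a format tag, metadata lines, the tab-separated label header,
    then one row of 0/1 digits per frame, and a trailing end marker so that
    truncation is detectable.
    """
    with open(path, "wt") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# trajectory_id\t{matrix.trajectory_id}\n")
        step = "" if matrix.frame_time_step is None else repr(matrix.frame_time_step)
        fh.write(f"# frame_time_step\t{step}\n")
        fh.write(f"# shape\t{matrix.n_frames}\t{matrix.n_contacts}\n")
        fh.write("\t".join(matrix.contact_labels) + "\n")
        for row in matrix.values:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
        fh.write("# end\n")


def read_fingerprint(path) -> FingerprintMatrix:
    """Inverse of :func:`write_fingerprint` (lossless round trip)."""
    with open(path, "rt") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or lines[0] != f"# {_FORMAT_TAG}":
        raise FingerprintFormatError(f"{path}: missing format tag {_FORMAT_TAG!r}")
    try:
        traj_id = lines[1].split("\t", 1)[1] if "\t" in lines[1] else ""
        step_field = lines[2].split("\t", 1)[1] if "\t" in lines[2] else ""
        step = float(step_field) if step_field else None
        shape_parts = lines[3].split("\t")
        if shape_parts[0] != "# shape" or len(shape_parts) != 3:
            raise ValueError("bad shape line")
        n_frames, n_contacts = int(shape_parts[1]), int(shape_parts[2])
        labels = lines[4].split("\t") if lines[4] else []
    except (IndexError, ValueError) as exc:
        raise FingerprintFormatError(f"{path}: corrupt header: {exc}") from None
    body = lines[5 : 5 + n_frames]
    if len(body) != n_frames or len(lines) < 5 + n_frames + 1 or lines[5 + n_frames] != "# end":
        raise FingerprintFormatError(f"{path}: truncated payload")
    if n_contacts == 0:
        values = np.zeros((n_frames, 0), dtype=np.uint8)
        labels = []
    else:
        values = np.zeros((n_frames, n_contacts), dtype=np.uint8)
        for i, row in enumerate(body):
            if len(row) != n_contacts:
                raise FingerprintFormatError(f"{path}: row {i} has wrong width")
            values[i] = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
    if not np.isin(values, (0, 1)).all():
        raise FingerprintFormatError(f"{path}: non-binary payload")
    return FingerprintMatrix(values, labels, traj_id, step)


def write_fingerprint_csv(matrix: FingerprintMatrix, path) -> None:
    """Interoperability export: plain CSV with a frame column."""
    import pandas as pd

    df = pd.DataFrame(matrix.values, columns=matrix.contact_labels)
    df.insert(0, "frame", np.arange(matrix.n_frames))
    df.to_csv(path, index=False)
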