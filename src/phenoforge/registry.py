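"""Stable identifier minting and obsoletion bookkeeping.

The registry is a flat TSV ledger mapping every issued CURIE to the
(pattern, bindings) tuple it was minted for. A binding tuple never
receives a second id and an id is never reused, so re-building from
identical inputs and registry state is fully reproducible.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .errors import MintingError, ObsoletionError
from .patterns import InstanceTable, PhenotypeClass, ID_COLUMN

Bindings = tuple[tuple[str, str], ...]


@dataclass
class IdRegistry:
    prefix: str = "PHENO"
    width: int = 7
    next_id: int = 1
    issued: dict[str, tuple[str, Bindings, str]] = field(default_factory=dict)
    # reverse index (pattern, bindings) -> CURIE
    _by_binding: dict[tuple[str, Bindings], str] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for curie, (pattern, bindings, _) in self.issued.items():
            self._by_binding[(pattern, bindings)] = curie

    def curie(self, number: int) -> str:
        if number >= 10**self.width:
            raise MintingError(
                f"id number {number} exceeds width {self.width}"
            )
        return f"{self.prefix}:{number:0{self.width}d}"

    def numeric(self, curie: str) -> int:
        prefix, _, digits = curie.partition(":")
        if prefix != self.prefix or not digits.isdigit():
            raise MintingError(f"{curie} does not match registry prefix {self.prefix}")
        return int(digits)

    def lookup(self, pattern_id: str, bindings: Bindings) -> str | None:
        return self._by_binding.get((pattern_id, bindings))

    def mint(self, pattern_id: str, bindings: Bindings, issued_on: str = "") -> str:
        existing = self.lookup(pattern_id, bindings)
        if existing is not None:
            return existing
        curie = self.curie(self.next_id)
        while curie in self.issued:  # skip ids imported out of band
            self.next_id += 1
            curie = self.curie(self.next_id)
        self.next_id += 1
        self.issued[curie] = (pattern_id, bindings, issued_on)
        self._by_binding[(pattern_id, bindings)] = curie
        return curie

    def register_existing(
        self, curie: str, pattern_id: str, bindings: Bindings, issued_on: str = ""
    ) -> None:
        if curie in self.issued:
            recorded_pattern, recorded_bindings, _ = self.issued[curie]
            if (recorded_pattern, recorded_bindings) != (pattern_id, bindings):
                raise MintingError(
                    f"provenance mismatch for {curie}: registry records "
                    f"{recorded_pattern} {dict(recorded_bindings)}, table claims "
                    f"{pattern_id} {dict(bindings)}"
                )
            return
        self.issued[curie] = (pattern_id, bindings, issued_on)
        self._by_binding[(pattern_id, bindings)] = curie
        self.next_id = max(self.next_id, self.numeric(curie) + 1)

    # -- persistence ---------------------------------------------------------
    def to_tsv(self) -> str:
        rows = [
            {
                "id": curie,
                "pattern": pattern,
                "bindings": "|".join(f"{k}={v}" for k, v in bindings),
                "issued_on": issued_on,
            }
            for curie, (pattern, bindings, issued_on) in sorted(self.issued.items())
        ]
        df = pd.DataFrame(rows, columns=["id", "pattern", "bindings", "issued_on"])
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str, prefix: str = "PHENO", width: int = 7) -> "IdRegistry":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
        reg = cls(prefix=prefix, width=width)
        for row in df.to_dict(orient="records"):
            bindings = tuple(
                tuple(pair.split("=", 1))
                for pair in row["bindings"].split("|")
                if pair
            )
            reg.register_existing(
                row["id"], row["pattern"], bindings, row.get("issued_on", "")
            )
        return reg


def mint_ids(
    tables: dict[str, InstanceTable], registry: IdRegistry, issued_on: str = ""
) -> dict[str, InstanceTable]:
    """Fill blank ``defined_class`` ids with consecutive new CURIEs.

    Tables are visited in pattern-id order, rows in table order (the
    deterministic order sync establishes), so identical inputs always
    issue identical ids. Existing ids are verified against the registry;
    a binding tuple seen before is given back its original id even when
    the row is new. Idempotent on its own output.
    """
    seen_ids: dict[str, str] = {}
    out: dict[str, InstanceTable] = {}
    for pid in sorted(tables):
        table = tables[pid]
        new_rows = []
        for row in table.rows:
            row = dict(row)
            bindings = tuple(sorted(table.bindings(row).items()))
            cid = row.get(ID_COLUMN, "")
            if cid:
                if cid in seen_ids:
                    raise MintingError(
                        f"id collision: {cid} claimed by tables "
                        f"{seen_ids[cid]} and {pid}"
                    )
                registry.register_existing(cid, pid, bindings, issued_on)
            else:
                cid = registry.mint(pid, bindings, issued_on)
                if cid in seen_ids:
                    raise MintingError(
                        f"id collision: {cid} claimed by tables "
                        f"{seen_ids[cid]} and {pid}"
                    )
                row[ID_COLUMN] = cid
            seen_ids[cid] = pid
            new_rows.append(row)
        out[pid] = InstanceTable(pid, table.columns, new_rows)
    return out


@dataclass
class ObsoletionTable:
    """Rows of (obsolete id, optional replacement, reason)."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, text: str) -> "ObsoletionTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
        return cls(
            [
                (row["id"], row.get("replaced_by", ""), row.get("reason", ""))
                for row in df.to_dict(orient="records")
            ]
        )

    def to_tsv(self) -> str:
        df = pd.DataFrame(
            [{"id": a, "replaced_by": b, "reason": c} for a, b, c in self.rows],
            columns=["id", "replaced_by", "reason"],
        )
        return df.to_csv(sep="\t", index=False)


def apply_obsoletions(
    classes: list[PhenotypeClass], obsoletions: ObsoletionTable
) -> list[PhenotypeClass]:
    """Mark classes obsolete per the obsoletion table.

    Obsoleted classes keep their id and (prefixed) label, lose their
    logical definition, gain ``replaced_by``, and remain in the release.
    Replacement targets must be live: pointing at a class obsoleted in the
    same run (or already obsolete) is an error — no transitive resolution.
    """
    by_id = {c.id: c for c in classes}
    obsoleted_now = {row[0] for row in obsoletions.rows}
    for cid, replaced_by, _ in obsoletions.rows:
        if cid not in by_id:
            raise ObsoletionError(f"cannot obsolete unknown id {cid}")
        if replaced_by:
            if replaced_by not in by_id:
                raise ObsoletionError(
                    f"{cid}: replaced_by target {replaced_by} is unknown"
                )
            if replaced_by in obsoleted_now or by_id[replaced_by].obsolete:
                raise ObsoletionError(
                    f"{cid}: replaced_by target {replaced_by} is itself obsolete"
                )
    replacements = {row[0]: row[1] for row in obsoletions.rows}
    out = []
    for c in classes:
        if c.id in replacements:
            label = c.label if c.label.startswith("obsolete ") else f"obsolete {c.label}"
            out.append(
                PhenotypeClass(
                    id=c.id,
                    label=label,
                    definition=c.definition,
                    synonyms=c.synonyms,
                    logical_definition=None,
                    provenance=c.provenance,
                    obsolete=True,
                    replaced_by=replacements[c.id] or None,
                )
            )
        else:
            out.append(c)
    return out
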