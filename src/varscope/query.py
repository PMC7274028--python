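"""Region and sample-expression grammars.

Regions are ``chrom:start-end``, ``chrom:pos``, or a gene id (widened by a
flank). Sample expressions are comma-separated mixes of accession-names,
``#groupId`` references, and inline definitions ``Name{a, b, c}``; ``#ALL``
expands to the whole catalog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    MalformedRegionError,
    NameCollisionError,
    UnknownNameError,
    UnresolvableQueryError,
)
from .io import RESERVED_IDS, GeneSpan, SampleCatalog

_COORDS_RE = re.compile(r"^(\d+)(?:-(\d+))?$")
_INLINE_RE = re.compile(r"^([^{}]+)\{([^{}]*)\}$")


@dataclass(frozen=True)
class RegionQuery:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    origin: str = "explicit"  # "explicit" | "gene"
    gene_id: Optional[str] = None
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise MalformedRegionError(
                f"bad region {self.chrom}:{self.start}-{self.end}"
            )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SampleSelection:
    members: list[str]
    defined_groups: dict[str, list[str]] = field(default_factory=dict)


def parse_region_spec(
    text: str,
    gene_index: Optional[dict[str, GeneSpan]] = None,
    flank: int = 0,
) -> RegionQuery:
    """Resolve region text to coordinates.

    The LAST colon splits chrom from coordinates, so dotted/underscored contig
    names survive. Flank applies only to gene-derived regions and is clipped
    at position 1. Thousands separators are rejected.
    """
    text = text.strip()
    if ":" in text:
        chrom, _, coords = text.rpartition(":")
        m = _COORDS_RE.match(coords)
        if m is None or not chrom:
            raise UnresolvableQueryError(f"cannot parse region {text!r}")
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if start > end:
            raise MalformedRegionError(f"start > end in {text!r}")
        return RegionQuery(chrom, start, end, origin="explicit")
    if gene_index and text in gene_index:
        span = gene_index[text]
        return RegionQuery(
            span.chrom,
            max(1, span.start - flank),
            span.end + flank,
            origin="gene",
            gene_id=text,
            flank=flank,
        )
    raise UnresolvableQueryError(
        f"{text!r} is neither coordinates nor a known gene id"
    )


def _split_top_level(text: str) -> list[str]:
    """Split on commas not enclosed in braces."""
    tokens, depth, buf = [], 0, []
    for ch in text:
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        if ch == "," and depth == 0:
            tokens.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    tokens.append("".join(buf))
    return [t.strip() for t in tokens if t.strip()]


def parse_sample_expression(text: str, catalog: SampleCatalog) -> SampleSelection:
    """Expand a sample expression against the catalog.

    Duplicates are removed keeping the first occurrence. Inline group names
    must not collide with catalog group ids or reserved ids.
    """
    members: list[str] = []
    seen: set[str] = set()
    defined: dict[str, list[str]] = {}
    accessions = set(catalog.accessions)

    def add(name: str) -> None:
        if name not in seen:
            seen.add(name)
            members.append(name)

    for token in _split_top_level(text):
        inline = _INLINE_RE.match(token)
        if inline:
            gname = inline.group(1).strip()
            if (
                gname in catalog.groups
                or gname in defined
                or gname in RESERVED_IDS
                or gname.lstrip("#") in RESERVED_IDS
            ):
                raise NameCollisionError(
                    f"inline group {gname!r} collides with an existing id"
                )
            body = [t.strip() for t in inline.group(2).split(",") if t.strip()]
            for acc in body:
                if acc not in accessions:
                    raise UnknownNameError(f"unknown accession {acc!r} in {gname!r}")
                add(acc)
            defined[gname] = body
        elif token == "#ALL":
            for acc in catalog.accessions:
                add(acc)
        elif token.startswith("#"):
            gid = token[1:]
            if gid not in catalog.groups:
                raise UnknownNameError(f"unknown group {token!r}")
            for acc in catalog.groups[gid]:
                add(acc)
        else:
            if token not in accessions:
                raise UnknownNameError(f"unknown accession or group {token!r}")
            add(token)
    return SampleSelection(members=members, defined_groups=defined)


def resolve_display(selection: SampleSelection, catalog: SampleCatalog) -> dict[str, str]:
    """Unique display labels per selected accession.

    Empty display names fall back to the accession name; colliding labels get
    an ordinal suffix ``(2)``, ``(3)``, … in selection order.
    """
    labels: dict[str, str] = {}
    counts: dict[str, int] = {}
    for acc in selection.members:
        base = catalog.display_of(acc)
        counts[base] = counts.get(base, 0) + 1
        labels[acc] = base if counts[base] == 1 else f"{base} ({counts[base]})"
    return labels
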