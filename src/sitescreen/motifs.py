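"""PROSITE-pattern matching and channel-feature assessment.

The pattern engine is a direct element-list matcher for the PROSITE
grammar subset used in practice: residue letters, the wildcard ``x``,
``[...]`` residue sets, ``{...}`` negated sets, ``(n)``/``(n,m)`` repeat
counts, hyphen separators and the ``<``/``>`` terminal anchors. All
overlapping matches are reported (one per start position), ascending by
start. The unknown residue X in a sequence matches wildcards and negated
sets but never a positive set or a different letter.

Channel features (selectivity filters, the cys-loop signature, the
pore-lining motif preceding TM2, the GPCR DRY motif) are checked either
over the whole protein or in a window anchored to a user-supplied
transmembrane-segment annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .seqio import SeqRecord


class PatternParseError(ValueError):
    """Unsupported or malformed PROSITE construct; message cites the token."""


@dataclass(frozen=True)
class _Element:
    kind: str  # letter | x | set | negset
    residues: frozenset[str]
    min_count: int
    max_count: int


@dataclass
class PrositePattern:
    pattern_id: str
    name: str
    raw: str
    elements: tuple[_Element, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_width(self) -> int:
        return sum(e.min_count for e in self.elements)

    @property
    def max_width(self) -> int:
        return sum(e.max_count for e in self.elements)

    @property
    def fixed_width(self) -> int | None:
        return self.min_width if self.min_width == self.max_width else None


@dataclass
class MotifHit:
    pattern_id: str
    seq_id: str
    start: int  # 1-based
    matched: str


def parse_pattern(raw: str, pattern_id: str = "", name: str = "") -> PrositePattern:
    """Compile a PROSITE pattern string."""
    text = raw.strip().rstrip(".")
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PatternParseError(f"empty pattern {raw!r}")

    elements: list[_Element] = []
    tokens = text.split("-")
    for tok in tokens:
        if not tok:
            raise PatternParseError(f"empty element in {raw!r}")
        body, min_c, max_c = _split_repeat(tok, raw)
        if body == "x":
            elements.append(_Element("x", frozenset(), min_c, max_c))
        elif body.startswith("[") and body.endswith("]"):
            residues = _residue_set(body[1:-1], raw)
            elements.append(_Element("set", residues, min_c, max_c))
        elif body.startswith("{") and body.endswith("}"):
            residues = _residue_set(body[1:-1], raw)
            elements.append(_Element("negset", residues, min_c, max_c))
        elif len(body) == 1 and body.isalpha() and body.isupper():
            elements.append(_Element("letter", frozenset(body), min_c, max_c))
        else:
            raise PatternParseError(
                f"unsupported token {tok!r} in pattern {raw!r}"
            )
    return PrositePattern(
        pattern_id or raw, name or pattern_id or raw, raw, tuple(elements),
        anchored_start, anchored_end,
    )


def _split_repeat(tok: str, raw: str) -> tuple[str, int, int]:
    if "(" not in tok:
        return tok, 1, 1
    if not tok.endswith(")"):
        raise PatternParseError(f"malformed repeat in {tok!r} ({raw!r})")
    body, _, count = tok[:-1].partition("(")
    if "," in count:
        lo, hi = count.split(",")
    else:
        lo = hi = count
    try:
        min_c, max_c = int(lo), int(hi)
    except ValueError as exc:
        raise PatternParseError(
            f"non-numeric repeat {count!r} in {raw!r}"
        ) from exc
    if min_c < 0 or max_c < min_c:
        raise PatternParseError(f"invalid repeat range in {tok!r} ({raw!r})")
    return body, min_c, max_c


def _residue_set(body: str, raw: str) -> frozenset[str]:
    residues = set(body)
    bad = {ch for ch in residues if not (ch.isalpha() and ch.isupper())}
    if bad:
        raise PatternParseError(
            f"invalid residue(s) {sorted(bad)} in set of {raw!r}"
        )
    return frozenset(residues)


def _char_matches(element: _Element, ch: str) -> bool:
    if element.kind == "x":
        return True
    if element.kind == "letter":
        return ch in element.residues
    if element.kind == "set":
        return ch in element.residues
    return ch not in element.residues  # negset; X matches (never in sets)


def _match_here(pattern: PrositePattern, seq: str, pos: int) -> str | None:
    """Greedy (maximal-repeat-first) match at a fixed start position."""
    elements = pattern.elements

    def rec(ei: int, p: int) -> int | None:
        if ei == len(elements):
            if pattern.anchored_end and p != len(seq):
                return None
            return p
        el = elements[ei]
        # count maximal run
        run = 0
        while (
            run < el.max_count
            and p + run < len(seq)
            and _char_matches(el, seq[p + run])
        ):
            run += 1
        for take in range(run, el.min_count - 1, -1):
            end = rec(ei + 1, p + take)
            if end is not None:
                return end
        return None

    end = rec(0, pos)
    return seq[pos:end] if end is not None else None


def scan(pattern: PrositePattern, seq: SeqRecord) -> list[MotifHit]:
    """All overlapping matches of the pattern, ascending 1-based start."""
    s = seq.residues
    hits = []
    starts = [0] if pattern.anchored_start else range(len(s))
    for pos in starts:
        if len(s) - pos < pattern.min_width:
            break
        matched = _match_here(pattern, s, pos)
        if matched is not None:
            hits.append(MotifHit(pattern.pattern_id, seq.id, pos + 1, matched))
    return hits


def read_pattern_catalog(path: str | None = None) -> list[PrositePattern]:
    """Read the PROSITE-style flat pattern catalog (shipped by default)."""
    if path is None:
        ref = resources.files("sitescreen.data") / "ptm_patterns.txt"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    patterns = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        pid, name, raw = ln.split("\t")
        patterns.append(parse_pattern(raw, pid, name))
    return patterns


@dataclass
class ChannelFeature:
    """A diagnostic channel motif, optionally anchored to an annotation.

    anchor "absolute": the whole protein is scanned. anchor
    "relative_to_annotation": the search window is placed against the
    named annotation — side "before_start" takes `window` residues
    immediately N-terminal of the annotation start (pore filters
    preceding TM2); side "at_end" takes `window` residues centred on the
    annotation end (the DRY motif at the end of TM3).
    """

    feature_id: str
    description: str
    expected_motif: str
    anchor: str = "absolute"
    annotation_key: str = ""
    side: str = "before_start"
    window: int = 10
    variant_motifs: tuple[str, ...] = ()


@dataclass
class FeatureReport:
    feature_id: str
    status: str  # present | variant | absent | not_evaluable
    observed: str
    position: int | None = None  # 1-based position of the observed motif


def _as_pattern(motif: str) -> PrositePattern:
    if any(ch in motif for ch in "-[{(x<>"):
        return parse_pattern(motif)
    return parse_pattern("-".join(motif))


def read_feature_catalog(path: str | None = None) -> list[ChannelFeature]:
    if path is None:
        ref = resources.files("sitescreen.data") / "channel_features.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        variants = tuple(
            v for v in row.get("variant_motifs", "").split(",") if v
        )
        out.append(
            ChannelFeature(
                feature_id=row["feature_id"],
                description=row["description"],
                expected_motif=row["expected_motif"],
                anchor=row["anchor"],
                annotation_key=row.get("annotation_key", ""),
                side=row.get("side", "before_start") or "before_start",
                window=int(row.get("window", "10") or 10),
                variant_motifs=variants,
            )
        )
    return out


def check_features(
    protein: SeqRecord,
    annotations: dict[str, tuple[int, int]],
    features: list[ChannelFeature],
) -> list[FeatureReport]:
    """Assess each channel feature on a protein.

    Relative features without their required annotation are reported
    "not_evaluable". A feature is "variant" when the expected motif is
    absent but one of its known variant motifs is found in the window.
    """
    reports = []
    for feat in features:
        if feat.anchor == "relative_to_annotation":
            if feat.annotation_key not in annotations:
                reports.append(
                    FeatureReport(feat.feature_id, "not_evaluable", "")
                )
                continue
            a_start, a_end = annotations[feat.annotation_key]
            if feat.side == "before_start":
                lo, hi = max(0, a_start - feat.window), a_start
            else:  # at_end
                lo = max(0, a_end - feat.window)
                hi = min(len(protein.residues), a_end + feat.window)
            window_seq = protein.residues[lo:hi]
            offset = lo
        else:
            window_seq = protein.residues
            offset = 0
        if not window_seq:
            reports.append(FeatureReport(feat.feature_id, "absent", ""))
            continue
        carrier = SeqRecord(protein.id, window_seq, alphabet="protein")
        hit = _first_hit(feat.expected_motif, carrier)
        if hit:
            reports.append(
                FeatureReport(
                    feat.feature_id, "present", hit.matched,
                    offset + hit.start,
                )
            )
            continue
        variant_hit = None
        for vm in feat.variant_motifs:
            variant_hit = _first_hit(vm, carrier)
            if variant_hit:
                break
        if variant_hit:
            reports.append(
                FeatureReport(
                    feat.feature_id, "variant", variant_hit.matched,
                    offset + variant_hit.start,
                )
            )
        else:
            observed = window_seq if feat.anchor != "absolute" else ""
            reports.append(FeatureReport(feat.feature_id, "absent", observed))
    return reports


def _first_hit(motif: str, seq: SeqRecord) -> MotifHit | None:
    hits = scan(_as_pattern(motif), seq)
    return hits[0] if hits else None


def write_hit_report(hits: list[MotifHit], path: str) -> None:
    """TSV of hits; "MOTIF pos" strings can be emitted verbatim."""
    with open(path, "w") as fh:
        fh.write("pattern\tseq\tpos\tmatched\n")
        for h in hits:
            fh.write(f"{h.pattern_id}\t{h.seq_id}\t{h.start}\t{h.matched}\n")


def kyte_doolittle_segments(
    protein: SeqRecord, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Propose transmembrane segments by hydropathy (advisory only).

    Windows whose mean Kyte-Doolittle hydropathy exceeds the threshold
    are merged into candidate segments; these are suggestions for the
    TM annotations the feature checks require, never auto-trusted.
    """
    kd = {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2, "X": 0.0,
    }
    s = protein.residues
    if len(s) < window:
        return []
    hot = []
    half = window // 2
    for i in range(len(s) - window + 1):
        mean = sum(kd.get(ch, 0.0) for ch in s[i:i + window]) / window
        if mean > threshold:
            hot.append(i + half)
    segments = []
    for c in hot:
        if segments and c - segments[-1][1] <= 3:
            segments[-1] = (segments[-1][0], c)
        else:
            segments.append((c, c))
    return [(max(0, a - half), min(len(s), b + half + 1)) for a, b in segments]
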