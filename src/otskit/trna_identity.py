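"""tRNA identity-element modelling: orthogonality screening of a suppressor
tRNA against host aminoacyl-tRNA synthetase (aaRS) recognition profiles, and
acceptor-stem mutation design.

tRNAs are represented by their base at each Sprinzl position (1-76, insertion
positions such as 47a permitted) together with the canonical acceptor-stem pair
map (1:72 through 7:66) and the variable-loop length.  An aaRS recognition
profile lists identity elements of three kinds: a required base at a position,
a required base pair across two paired positions, and structural features (for
example the extended variable loop required by the seryl-tRNA synthetase).  An
aaRS is flagged as a potential mis-recognition risk when enough of its elements
match the query tRNA and no structural element is unmet.

The shipped catalog encodes the acceptor-stem/discriminator overlap of the
pSer suppressor tRNA with the glycyl- and threonyl-tRNA synthetases (G1:C72,
C2:G71, U73) and the serine-system elements from the primary literature; its
rows are marked paper-stated versus literature-supplemented and users can
extend the TSV.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

ACCEPTOR_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 72), (2, 71), (3, 70), (4, 69), (5, 68), (6, 67), (7, 66),
)
WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
BASES = ("A", "C", "G", "U")


def _pos_sort_key(pos: str) -> tuple[int, str]:
    m = re.fullmatch(r"(\d+)([a-z]*)", pos)
    if not m:
        raise ValueError(f"invalid Sprinzl position {pos!r}")
    return int(m.group(1)), m.group(2)


@dataclass
class TRNASeq:
    """A tRNA keyed by Sprinzl position.

    ``bases`` maps position labels ('1'..'76', insertions like '47a') to bases;
    acceptor-stem pairs must be complementary (G:U tolerated with a warning and
    recorded in ``wobble_pairs``); the discriminator (73) and a 3-base
    anticodon (34-36) must be present.
    """

    name: str
    bases: dict[str, str]
    variable_loop_len: int = 0
    wobble_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bases = {str(k): v.upper() for k, v in self.bases.items()}
        for pos, b in self.bases.items():
            if b not in BASES:
                raise ValueError(f"invalid base {b!r} at position {pos}")
        if "73" not in self.bases:
            raise ValueError("discriminator base (position 73) missing")
        for p in ("34", "35", "36"):
            if p not in self.bases:
                raise ValueError("anticodon positions 34-36 must all be present")
        self.wobble_pairs = []
        for p5, p3 in ACCEPTOR_PAIRS:
            b5, b3 = self.bases.get(str(p5)), self.bases.get(str(p3))
            if b5 is None or b3 is None:
                continue
            if (b5, b3) in WOBBLE:
                warnings.warn(
                    f"{self.name}: G:U pair at {p5}:{p3} tolerated", stacklevel=2
                )
                self.wobble_pairs.append((p5, p3))
            elif (b5, b3) not in WATSON_CRICK:
                raise ValueError(
                    f"{self.name}: acceptor pair {p5}:{p3} ({b5}:{b3}) "
                    "is not complementary"
                )

    def base_at(self, pos: str | int) -> str:
        key = str(pos)
        if key not in self.bases:
            raise KeyError(f"{self.name} has no Sprinzl position {key}")
        return self.bases[key]

    @property
    def anticodon(self) -> str:
        return "".join(self.bases[p] for p in ("34", "35", "36"))

    def sequence(self) -> str:
        return "".join(
            self.bases[p] for p in sorted(self.bases, key=_pos_sort_key)
        )


@dataclass(frozen=True)
class IdentityElement:
    """One aaRS recognition element.

    kind 'base': required base at ``pos5``; kind 'base_pair': required
    ``required`` like 'G:C' across (pos5, pos3); kind 'structural': a named
    feature predicate, currently ``variable_loop`` length >= ``threshold``.
    """

    kind: str
    pos5: str = ""
    pos3: str = ""
    required: str = ""
    feature: str = ""
    threshold: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("base", "base_pair", "structural"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "base" and self.required not in BASES:
            raise ValueError("base element needs a single required base")
        if self.kind == "base_pair":
            parts = self.required.split(":")
            if len(parts) != 2 or any(p not in BASES for p in parts):
                raise ValueError("base_pair element needs required like 'G:C'")

    def describe(self) -> str:
        if self.kind == "base":
            return f"{self.required}{self.pos5}"
        if self.kind == "base_pair":
            b5, b3 = self.required.split(":")
            return f"{b5}{self.pos5}:{b3}{self.pos3}"
        return f"{self.feature}>={self.threshold:g}"


@dataclass
class RecognitionProfile:
    """Identity elements of one aaRS plus the flag threshold (default 3, the
    number of shared acceptor-stem/discriminator elements that marked the host
    Gly/Thr systems as mis-recognition risks)."""

    aars: str
    elements: list[IdentityElement]
    flag_threshold: int = 3

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a recognition profile needs at least one element")

    def structural_elements(self) -> list[IdentityElement]:
        return [e for e in self.elements if e.kind == "structural"]


def element_matches(seq: TRNASeq, element: IdentityElement) -> bool:
    """Exact evaluation of one element on one tRNA; missing positions raise."""
    if element.kind == "base":
        return seq.base_at(element.pos5) == element.required
    if element.kind == "base_pair":
        b5, b3 = element.required.split(":")
        return seq.base_at(element.pos5) == b5 and seq.base_at(element.pos3) == b3
    if element.feature == "variable_loop":
        return seq.variable_loop_len >= element.threshold
    raise ValueError(f"unknown structural feature {element.feature!r}")


def overlap_elements(seq: TRNASeq, profile: RecognitionProfile) -> set[IdentityElement]:
    """Subset of the profile's elements matching the sequence."""
    return {e for e in profile.elements if element_matches(seq, e)}


@dataclass
class ScreenEntry:
    aars: str
    matched: int
    flag_threshold: int
    structural_unmet: bool
    flagged: bool
    matched_elements: set[IdentityElement]


def screen_host_recognition(
    seq: TRNASeq, profiles: list[RecognitionProfile]
) -> list[ScreenEntry]:
    """Flag every aaRS whose matched-element count reaches its threshold and
    whose structural requirements are all met; sorted by matched count
    descending, then name."""
    if not profiles:
        raise ValueError("need at least one recognition profile")
    entries = []
    for prof in profiles:
        matched = overlap_elements(seq, prof)
        structural_unmet = any(
            e not in matched for e in prof.structural_elements()
        )
        flagged = len(matched) >= prof.flag_threshold and not structural_unmet
        entries.append(
            ScreenEntry(
                aars=prof.aars,
                matched=len(matched),
                flag_threshold=prof.flag_threshold,
                structural_unmet=structural_unmet,
                flagged=flagged,
                matched_elements=matched,
            )
        )
    entries.sort(key=lambda e: (-e.matched, e.aars))
    return entries


def flip_base_pair(seq: TRNASeq, pair: tuple[int, int]) -> TRNASeq:
    """Swap the bases of one acceptor-stem pair (e.g. C2:G71 -> G2:C71); an
    involution that leaves every other position unchanged."""
    if tuple(pair) not in ACCEPTOR_PAIRS:
        raise ValueError(f"{pair} is not an acceptor-stem pair")
    p5, p3 = str(pair[0]), str(pair[1])
    if p5 not in seq.bases or p3 not in seq.bases:
        raise ValueError(f"{seq.name} lacks positions {pair[0]} and/or {pair[1]}")
    bases = dict(seq.bases)
    bases[p5], bases[p3] = bases[p3], bases[p5]
    return replace(
        seq,
        name=f"{seq.name}[{pair[0]}:{pair[1]}flip]",
        bases=bases,
    )


@dataclass
class MutationCandidate:
    description: str
    mutant: TRNASeq
    host_match_reduction: int


def _total_host_matches(seq: TRNASeq, host_profiles: list[RecognitionProfile]) -> int:
    return sum(len(overlap_elements(seq, p)) for p in host_profiles)


def propose_orthogonalizing_mutations(
    seq: TRNASeq,
    cognate: RecognitionProfile,
    host_profiles: list[RecognitionProfile],
) -> list[MutationCandidate]:
    """Single acceptor-stem flips and discriminator changes that keep every
    cognate element matched while strictly reducing the summed host
    identity-element matches; ranked by the size of the reduction."""
    baseline = _total_host_matches(seq, host_profiles)
    candidates: list[MutationCandidate] = []

    def consider(mutant: TRNASeq, description: str) -> None:
        if not all(element_matches(mutant, e) for e in cognate.elements):
            return
        reduction = baseline - _total_host_matches(mutant, host_profiles)
        if reduction > 0:
            candidates.append(MutationCandidate(description, mutant, reduction))

    for pair in ACCEPTOR_PAIRS:
        p5, p3 = str(pair[0]), str(pair[1])
        if p5 not in seq.bases or p3 not in seq.bases:
            continue
        if seq.bases[p5] == seq.bases[p3]:
            continue  # flip would be a no-op
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mutant = flip_base_pair(seq, pair)
        b5, b3 = seq.bases[p5], seq.bases[p3]
        consider(mutant, f"flip({pair[0]},{pair[1]}) {b5}{pair[0]}:{b3}{pair[1]}"
                         f"->{b3}{pair[0]}:{b5}{pair[1]}")

    disc = seq.bases["73"]
    for b in BASES:
        if b == disc:
            continue
        bases = dict(seq.bases)
        bases["73"] = b
        mutant = replace(seq, name=f"{seq.name}[{disc}73{b}]", bases=bases)
        consider(mutant, f"discriminator {disc}73->{b}73")

    candidates.sort(key=lambda c: (-c.host_match_reduction, c.description))
    return candidates


# ---------------------------------------------------------------------------
# I/O and shipped fixtures
# ---------------------------------------------------------------------------

def read_trna_positions(
    path: str | Path, name: str | None = None
) -> TRNASeq:
    """Read a tRNA from a positions TSV (columns sprinzl_position, base).

    The variable-loop length is the number of positions present in the 44-48
    block including lettered insertions (44..48, 47a, 47b, ...).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"sprinzl_position", "base"}.issubset(df.columns):
        raise ValueError("positions TSV needs columns sprinzl_position, base")
    bases = dict(zip(df["sprinzl_position"], df["base"]))
    vloop = sum(1 for p in bases if 44 <= _pos_sort_key(p)[0] <= 48)
    return TRNASeq(
        name=name or Path(path).stem,
        bases=bases,
        variable_loop_len=vloop,
    )


def read_element_catalog(path: str | Path | None = None) -> list[RecognitionProfile]:
    """Read an identity-element catalog TSV (columns aars, kind, pos5, pos3,
    required, structural_feature, threshold, flag_threshold, source); defaults
    to the shipped catalog."""
    if path is None:
        path = resources.files("otskit.data") / "identity_elements.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    profiles: dict[str, list[IdentityElement]] = {}
    thresholds: dict[str, int] = {}
    for row in df.itertuples():
        el = IdentityElement(
            kind=row.kind,
            pos5=str(row.pos5),
            pos3=str(row.pos3),
            required=str(row.required),
            feature=str(row.structural_feature),
            threshold=float(row.threshold) if row.threshold else 0.0,
            source=str(row.source),
        )
        profiles.setdefault(row.aars, []).append(el)
        if getattr(row, "flag_threshold", ""):
            thresholds[row.aars] = int(row.flag_threshold)
    return [
        RecognitionProfile(
            aars=aars, elements=els, flag_threshold=thresholds.get(aars, 3)
        )
        for aars, els in sorted(profiles.items())
    ]


def load_pser_trna() -> TRNASeq:
    """The shipped pSer suppressor tRNA fixture (synthetic filler outside the
    documented identity positions; see the data file's header)."""
    path = resources.files("otskit.data") / "trna_pser_synthetic.tsv"
    return read_trna_positions(path, name="tRNA-pSer")


def write_trna_fasta(seqs: list[TRNASeq], path: str | Path) -> None:
    """FASTA output of (mutated) tRNAs, bases in Sprinzl order."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s.sequence()), id=s.name.replace(" ", "_"), description="")
        for s in seqs
    ]
    seqio_write(records, str(path), "fasta")


def write_screen_results(entries: list[ScreenEntry], path: str | Path) -> None:
    rows = [
        {
            "aars": e.aars,
            "matched": e.matched,
            "flag_threshold": e.flag_threshold,
            "structural_unmet": e.structural_unmet,
            "flagged": e.flagged,
            "matched_elements": ";".join(sorted(m.describe() for m in e.matched_elements)),
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
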