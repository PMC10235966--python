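"""miRNA seed-site scanning on 3'UTRs and duplex rendering.

Canonical miRNA target sites are defined by Watson-Crick complementarity
between the miRNA *seed* (positions 2-8, counted from the 5' end) and the
mRNA.  Reading the mRNA site 5'->3', the four canonical types are:

    6mer     perfect match to miRNA positions 2-7
    7mer-m8  perfect match to positions 2-8
    7mer-A1  match to 2-7 plus an adenosine opposite miRNA position 1
    8mer     match to 2-8 plus the A1 adenosine

Sites are anchored on occurrences of the 6mer core (reverse complement of
miRNA 2-7); each core occurrence is assigned its single highest-ranking type
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  G:U wobbles are never accepted inside the
seed match; the duplex renderer marks them (':') only in the flanks.
Coordinates are 1-based inclusive on the UTR as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

from .errors import ValidationError

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}  # lower = stronger

_RNA = set("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


def _clean_rna(seq: str, what: str) -> str:
    s = seq.upper().replace(" ", "")
    if "T" in s:
        warnings.warn(f"{what}: DNA alphabet detected, converting T->U", stacklevel=3)
        s = s.replace("T", "U")
    bad = set(s) - _RNA
    if bad or not s:
        raise ValidationError(f"{what}: invalid RNA alphabet characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class MicroRNA:
    name: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        self.sequence = _clean_rna(self.sequence, f"miRNA {self.name}")
        if len(self.sequence) < 19:
            raise ValidationError("mature miRNAs are expected to be >= 19 nt")

    @property
    def seed(self) -> str:
        """Positions 2-8, 5'->3'."""
        return self.sequence[1:8]


@dataclass
class UtrRecord:
    gene: str
    sequence: str  # RNA, 5'->3'; 1-based inclusive coordinates

    def __post_init__(self) -> None:
        self.sequence = _clean_rna(self.sequence, f"UTR {self.gene}")


@dataclass(frozen=True)
class SeedSite:
    gene: str
    site_type: str
    start: int  # 1-based inclusive
    end: int
    site_seq: str
    pairing: str = ""  # filled in by render_duplex


def _site_layout(mirna: MicroRNA) -> tuple[str, str]:
    """(core, m8) = (rc of miRNA 2-7, complement of miRNA position 8)."""
    core = reverse_complement(mirna.sequence[1:7])
    m8 = _COMPLEMENT[mirna.sequence[7]]
    return core, m8


def find_seed_sites(mirna: MicroRNA, utr: UtrRecord) -> list[SeedSite]:
    """All seed-match sites in one UTR, one (highest-ranking) type per core hit."""
    core, m8 = _site_layout(mirna)
    seq = utr.sequence
    sites: list[SeedSite] = []
    start = 0
    while True:
        i = seq.find(core, start)  # 0-based start of the 6mer core
        if i < 0:
            break
        start = i + 1
        has_m8 = i - 1 >= 0 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            s, e, t = i - 1, i + 6, "8mer"
        elif has_m8:
            s, e, t = i - 1, i + 5, "7mer-m8"
        elif has_a1:
            s, e, t = i, i + 6, "7mer-A1"
        else:
            s, e, t = i, i + 5, "6mer"
        sites.append(SeedSite(utr.gene, t, s + 1, e + 1, seq[s : e + 1]))
    return sites


def _pair_char(target_nt: str, mirna_nt: str) -> str:
    if _COMPLEMENT[mirna_nt] == target_nt:
        return "|"
    if (target_nt, mirna_nt) in _WOBBLE:
        return ":"
    return " "


def render_duplex(mirna: MicroRNA, utr: UtrRecord, site: SeedSite) -> str:
    """Three-line duplex text: target 5'->3', pairing row, miRNA 3'->5'.

    The full miRNA is aligned antiparallel with position 1 opposite the
    target nucleotide just 3' of the seed core (the A1 position).  Site
    nucleotides are uppercase, flanking context lowercase.  '|' marks
    Watson-Crick pairs; ':' marks G:U wobbles (flanks only by construction,
    since seed matches are wobble-free).
    """
    seq = utr.sequence
    if not (1 <= site.start <= site.end <= len(seq)):
        raise ValidationError("site lies outside the UTR")
    mir = mirna.sequence
    n = len(mir)
    # 0-based index of the target position opposite miRNA position 1:
    core_end0 = site.end - 1 if site.site_type in ("8mer", "7mer-A1") else site.end
    window0 = core_end0 - n + 1  # target index opposite miRNA 3' end

    target_chars, pair_chars, mir_chars = [], [], []
    for col in range(n):
        ti = window0 + col
        m_nt = mir[n - 1 - col]  # miRNA printed 3'->5'
        if 0 <= ti < len(seq):
            t_nt = seq[ti]
            in_site = site.start - 1 <= ti <= site.end - 1
            target_chars.append(t_nt if in_site else t_nt.lower())
            pair_chars.append(_pair_char(t_nt, m_nt))
        else:
            target_chars.append("-")
            pair_chars.append(" ")
        mir_chars.append(m_nt)
    lines = [
        f"5' {''.join(target_chars)} 3'  {utr.gene} ({site.site_type} {site.start}-{site.end})",
        f"   {''.join(pair_chars)}",
        f"3' {''.join(mir_chars)} 5'  {mirna.name}",
    ]
    return "\n".join(lines)


def count_sites_per_gene(
    mirna: MicroRNA, utrs, allow_duplicate_genes: bool = False
) -> dict[str, dict[str, int]]:
    """Per-gene table of site counts by type (plus a total)."""
    utrs = list(utrs)
    if not utrs:
        raise ValidationError("empty UTR set")
    seen: set[str] = set()
    table: dict[str, dict[str, int]] = {}
    for idx, utr in enumerate(utrs):
        name = utr.gene
        if name in seen:
            if not allow_duplicate_genes:
                raise ValidationError(f"duplicate gene name {name!r}")
            name = f"{name}.{idx}"
        seen.add(name)
        counts = {t: 0 for t in SITE_TYPES}
        for site in find_seed_sites(mirna, utr):
            counts[site.site_type] += 1
        counts["total"] = sum(counts[t] for t in SITE_TYPES)
        table[name] = counts
    return table
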