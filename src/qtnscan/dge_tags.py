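"""Digital gene expression (DGE) tag processing.

A DGE tag is the 21-base signature CATG + 17 nt found immediately at an
NlaIII restriction site (CATG) of a transcript. Expression is quantified by
counting observed tags against a virtual library of every possible tag on
both strands of a reference transcript set, then normalizing counts to TPM
(tags per million clean tags).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "TAG_LENGTH",
    "TagLibrary",
    "build_virtual_tag_library",
    "map_tags",
    "counts_to_tpm",
]

TAG_LENGTH = 21  # CATG anchor + 17 downstream bases
_ANCHOR = "CATG"

_ENC = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i + 1  # 0 is reserved for N / unknown (never matches)


def _encode(tag: str) -> np.ndarray:
    return _ENC[np.frombuffer(tag.encode("ascii"), dtype=np.uint8)]


@dataclass
class TagLibrary:
    """Virtual tag library: tag sequence -> unique gene, plus ambiguous tags."""

    tags: dict           # tag -> (gene, strand, offset) for unambiguous tags
    ambiguous: set = field(default_factory=set)
    genes: list = field(default_factory=list)
    # packed encodings of the unambiguous tags, for mismatch search
    _codes: np.ndarray = None
    _tag_list: list = None

    def __post_init__(self) -> None:
        self._tag_list = list(self.tags)
        if self._tag_list:
            self._codes = np.stack([_encode(t) for t in self._tag_list])
        else:
            self._codes = np.zeros((0, TAG_LENGTH), dtype=np.int8)

    def __len__(self) -> int:
        return len(self.tags)


def _extract_tags(seq: str):
    """Yield (tag, offset) for every anchored 21-mer in one strand of a sequence."""
    start = 0
    while True:
        i = seq.find(_ANCHOR, start)
        if i < 0:
            return
        if len(seq) - i >= TAG_LENGTH:
            yield seq[i:i + TAG_LENGTH], i
        start = i + 1


def build_virtual_tag_library(transcripts) -> TagLibrary:
    """Build the virtual NlaIII tag library from FASTA records.

    ``transcripts`` is a FASTA path/handle or an iterable of (gene_id,
    sequence) pairs. Every CATG occurrence on both strands with at least 17
    downstream bases yields a tag; tags found in more than one gene are
    placed in the ambiguous set and excluded from counting. Tags containing
    a base outside {A,C,G,T} are dropped (N never matches).
    """
    if isinstance(transcripts, (str,)) or hasattr(transcripts, "read"):
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(transcripts, "fasta")]
    else:
        records = [(gid, str(s)) for gid, s in transcripts]
    if not records:
        raise ValueError("empty transcript set")

    seen: dict[str, tuple] = {}
    ambiguous: set[str] = set()
    genes: list[str] = []
    for gene, seq in records:
        if gene not in genes:
            genes.append(gene)
        seq = seq.upper()
        for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
            for tag, off in _extract_tags(s):
                if any(b not in "ACGT" for b in tag):
                    continue
                if tag in ambiguous:
                    continue
                if tag in seen and seen[tag][0] != gene:
                    ambiguous.add(tag)
                    del seen[tag]
                elif tag not in seen:
                    seen[tag] = (gene, strand, off)
    return TagLibrary(tags=seen, ambiguous=ambiguous, genes=genes)


def map_tags(observed, lib: TagLibrary, max_mismatch: int = 1):
    """Count observed 21-base tags against the library.

    ``observed`` is a mapping tag -> multiplicity (or an iterable of tags).
    Exact matches are assigned first; otherwise a tag is assigned to the
    unique library tag within ``max_mismatch`` Hamming distance. Ties
    between equally close library tags of different genes, ambiguous library
    tags, and distances beyond the limit leave a tag unmapped. Returns
    (per-gene counts Series, unmapped count).
    """
    if not isinstance(observed, (dict, Counter)):
        observed = Counter(observed)
    counts = {gene: 0 for gene in lib.genes}
    unmapped = 0
    for tag, mult in observed.items():
        if len(tag) != TAG_LENGTH:
            raise ValueError(f"tag {tag!r} is not {TAG_LENGTH} bases long")
        if tag in lib.ambiguous:
            unmapped += mult
            continue
        hit = lib.tags.get(tag)
        if hit is None and max_mismatch > 0 and len(lib) > 0:
            code = _encode(tag)
            # position with code 0 (N) mismatches everything, including N
            mm = np.sum((lib._codes != code) | (lib._codes == 0) | (code == 0),
                        axis=1)
            best = int(mm.min())
            if best <= max_mismatch:
                cand = np.flatnonzero(mm == best)
                cand_genes = {lib.tags[lib._tag_list[i]][0] for i in cand}
                if len(cand) == 1 or len(cand_genes) == 1:
                    hit = lib.tags[lib._tag_list[cand[0]]]
        if hit is None:
            unmapped += mult
        else:
            counts[hit[0]] += mult
    return pd.Series(counts, name="count"), unmapped


def counts_to_tpm(counts: pd.DataFrame, clean_totals=None) -> pd.DataFrame:
    """Normalize per-gene tag counts to tags-per-million clean tags.

    ``counts`` is genes x samples. ``clean_totals`` gives the per-sample
    clean-tag totals (the pre-mapping denominator); when omitted the mapped
    column sums are used, in which case every column sums to exactly 1e6.
    """
    counts = counts.astype(float)
    if clean_totals is None:
        totals = counts.sum(axis=0)
    else:
        totals = pd.Series(clean_totals, index=counts.columns, dtype=float) \
            if not isinstance(clean_totals, pd.Series) else clean_totals.astype(float)
        totals = totals.reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("every sample needs a positive clean-tag total")
    return counts.div(totals, axis=1) * 1e6
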