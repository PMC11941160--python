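"""Pairwise paralogue sequence identity (protein and DNA).

Local (Smith-Waterman) alignment with BLAST-default scoring: BLOSUM62 with
gap open 11 / extend 1 for proteins; match +2 / mismatch -3 with gap open
5 / extend 2 for DNA.  Percent identity is matches over alignment columns
(gap columns included) of the best local alignment.  A small fetch helper
can retrieve CDS/protein sequences by systematic yeast gene name from NCBI
(network access required; never used implicitly).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
_DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class IdentityResult:
    pair: tuple[str, str]
    mode: str  # protein | dna
    percent_identity: float
    alignment_length: int
    score: float
    n_identical: int


def _validate(seq: str, alphabet: set, mode: str, which: str) -> str:
    seq = str(seq).upper().replace("\n", "").replace(" ", "")
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"invalid {mode} character {ch!r} at position {i} of {which} sequence"
            )
    return seq


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # BLAST gap cost 11 + k: first gapped column 12, each further 1
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
    elif mode == "dna":
        aligner.match_score = 2.0
        aligner.mismatch_score = -3.0
        aligner.open_gap_score = -7.0  # BLASTN gap cost 5 + 2k
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    mode: str = "protein",
    name_a: str = "a",
    name_b: str = "b",
) -> IdentityResult:
    """Percent identity over the best local alignment of two sequences."""
    alphabet = _PROTEIN_ALPHABET if mode == "protein" else _DNA_ALPHABET
    sa = _validate(seq_a, alphabet, mode, name_a)
    sb = _validate(seq_b, alphabet, mode, name_b)
    aligner = _aligner(mode)
    alignment = aligner.align(sa, sb)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return IdentityResult(
        pair=(name_a, name_b),
        mode=mode,
        percent_identity=float(identity),
        alignment_length=int(columns),
        score=float(alignment.score),
        n_identical=int(counts.identities),
    )


def identity_from_fasta(path_a, path_b, mode: str = "protein") -> IdentityResult:
    """Identity of the first records of two FASTA files."""
    rec_a = next(SeqIO.parse(path_a, "fasta"))
    rec_b = next(SeqIO.parse(path_b, "fasta"))
    return pairwise_identity(
        str(rec_a.seq), str(rec_b.seq), mode=mode, name_a=rec_a.id, name_b=rec_b.id
    )


def fetch_yeast_sequence(
    systematic_name: str, mode: str = "protein", timeout: float = 15.0
) -> str:
    """Fetch a S. cerevisiae CDS or protein sequence from NCBI by name.

    Requires network access; raises a ConnectionError when offline.
    """
    import io
    import urllib.error
    import urllib.parse
    import urllib.request

    term = f"{systematic_name}[Gene Name] AND Saccharomyces cerevisiae S288C[Organism]"
    db = "protein" if mode == "protein" else "nuccore"
    base = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
    try:
        with urllib.request.urlopen(
            f"{base}/esearch.fcgi?" + urllib.parse.urlencode({"db": db, "term": term}),
            timeout=timeout,
        ) as fh:
            body = fh.read().decode()
        ids = [
            part.split("</Id>")[0]
            for part in body.split("<Id>")[1:2]
        ]
        if not ids:
            raise ValueError(f"no {db} record found for {systematic_name!r}")
        with urllib.request.urlopen(
            f"{base}/efetch.fcgi?"
            + urllib.parse.urlencode(
                {"db": db, "id": ids[0], "rettype": "fasta", "retmode": "text"}
            ),
            timeout=timeout,
        ) as fh:
            fasta = fh.read().decode()
    except (urllib.error.URLError, OSError) as exc:
        raise ConnectionError(
            f"cannot fetch {systematic_name!r} from NCBI (no network access?)"
        ) from exc
    rec = next(SeqIO.parse(io.StringIO(fasta), "fasta"))
    return str(rec.seq)
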