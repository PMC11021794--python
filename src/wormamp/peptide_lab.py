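"""Peptide physicochemistry and antimicrobial-candidate triage.

Covers the desk work of an AMP discovery pipeline: signal-peptide removal,
net charge at a given pH (Henderson-Hasselbalch over the ionizable groups),
isoelectric point (root of the charge curve), amino-acid composition, molar
extinction coefficient at 280 nm with Beer-Lambert concentration, disulfide
detection from structure coordinates (SG-SG distances), and consensus
screening of predictor score tables (sequence-similarity E-values, ampir and
MultiPep probabilities) against the standard retention thresholds.

Net charge at pH is

    Z(pH) = sum_basic  n_i / (1 + 10^(pH - pKa_i))
          - sum_acidic n_i / (1 + 10^(pKa_i - pH))

with basic groups {N-terminus, His, Lys, Arg} and acidic {C-terminus, Asp,
Glu, Cys, Tyr}.  Z is strictly decreasing in pH, so the pI is its unique
root, found here by bisection.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "PeptideRecord", "PkaSet", "ScoreRow", "AtomRecord", "ScreenThresholds",
    "PKA_PRESETS", "mature_sequence", "net_charge", "isoelectric_point",
    "composition", "extinction_coefficient", "concentration",
    "detect_disulfides", "read_pdb_sg_atoms", "screen_candidates",
    "read_fasta", "bundled_score_table", "molar_mass",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PeptideRecord:
    id: str
    residues: str
    species: str = ""
    accession: str | None = None
    signal_range: tuple[int, int] | None = None  # 1-based inclusive

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        if self.signal_range is not None:
            s, e = self.signal_range
            if not (1 <= s <= e <= len(self.residues)):
                raise ValueError("signal_range outside sequence bounds")


@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa table driving charge and pI."""

    name: str
    n_term: float
    c_term: float
    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float

    def __post_init__(self) -> None:
        for f in ("n_term", "c_term", "D", "E", "C", "Y", "H", "K", "R"):
            v = getattr(self, f)
            if not 0 < v < 14:
                raise ValueError(f"pKa {f}={v} outside (0, 14)")


# Bjellqvist-style table (the common "expasy" values); selectable by name so
# the preset can be swapped to match other calculators.
PKA_PRESETS: dict[str, PkaSet] = {
    "bjellqvist": PkaSet("bjellqvist", n_term=9.69, c_term=2.34, D=3.65,
                         E=4.25, C=8.30, Y=10.07, H=6.00, K=10.53, R=12.48),
    # Lehninger textbook values, as a second reference point
    "lehninger": PkaSet("lehninger", n_term=9.69, c_term=2.34, D=3.86,
                        E=4.25, C=8.33, Y=10.07, H=6.00, K=10.53, R=12.48),
    # the Expasy/ProtParam-style table (no positional corrections); closest
    # to what most online pI calculators report
    "expasy": PkaSet("expasy", n_term=7.50, c_term=3.55, D=4.05, E=4.45,
                     C=9.00, Y=10.00, H=5.98, K=10.00, R=12.00),
}

_ACIDIC = "DECY"
_BASIC = "HKR"


def mature_sequence(rec: PeptideRecord) -> PeptideRecord:
    """Remove the annotated signal peptide; identity if none is annotated."""
    if rec.signal_range is None:
        return rec
    s, e = rec.signal_range
    remaining = rec.residues[:s - 1] + rec.residues[e:]
    if not remaining:
        raise ValueError("signal_range covers the whole sequence")
    return replace(rec, id=f"{rec.id}_mature", residues=remaining,
                   signal_range=None)


def net_charge(residues: str, pH: float = 7.4,
               pka: PkaSet | str = "bjellqvist", strict: bool = True) -> float:
    """Net charge (elementary charges) at ``pH`` including free termini."""
    if not 0 < pH < 14:
        raise ValueError("pH must be in (0, 14)")
    if isinstance(pka, str):
        pka = PKA_PRESETS[pka]
    seq = residues.upper()
    unknown = set(seq) - set(AMINO_ACIDS)
    if unknown:
        if strict:
            raise ValueError(f"unknown residues {sorted(unknown)} (strict mode)")
        seq = "".join(c for c in seq if c in AMINO_ACIDS)
    if not seq:
        raise ValueError("empty sequence")

    def basic(pk: float, n: float = 1.0) -> float:
        return n / (1.0 + 10.0 ** (pH - pk))

    def acidic(pk: float, n: float = 1.0) -> float:
        return n / (1.0 + 10.0 ** (pk - pH))

    z = basic(pka.n_term) - acidic(pka.c_term)
    for aa in _BASIC:
        z += basic(getattr(pka, aa), seq.count(aa))
    for aa in _ACIDIC:
        z -= acidic(getattr(pka, aa), seq.count(aa))
    return z


def isoelectric_point(residues: str, pka: PkaSet | str = "bjellqvist",
                      tol: float = 0.01, strict: bool = True) -> float:
    """pH at which the net charge is zero, by bisection on (0, 14).

    The charge curve is strictly decreasing, so the root is unique whenever
    the sequence carries ionizable groups of both signs (always true when
    both termini are free).
    """
    lo, hi = 1e-6, 14.0 - 1e-6
    z_lo = net_charge(residues, lo, pka, strict)
    z_hi = net_charge(residues, hi, pka, strict)
    if z_lo <= 0 or z_hi >= 0:
        raise ValueError("pI undefined: net charge does not change sign on (0, 14)")
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        if net_charge(residues, mid, pka, strict) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition(residues: str) -> dict[str, float]:
    """Percent composition per amino acid; percentages sum to 100."""
    seq = residues.upper()
    if not seq:
        raise ValueError("empty sequence")
    return {aa: 100.0 * seq.count(aa) / len(seq)
            for aa in sorted(set(seq))}


def extinction_coefficient(residues: str, cystines_paired: bool = False) -> float:
    """Molar extinction at 280 nm (M^-1 cm^-1): 5500 per Trp, 1490 per Tyr,
    125 per cystine (only when cysteines are assumed oxidised/paired)."""
    seq = residues.upper()
    eps = 5500.0 * seq.count("W") + 1490.0 * seq.count("Y")
    if cystines_paired:
        eps += 125.0 * (seq.count("C") // 2)
    return eps


def molar_mass(residues: str) -> float:
    """Average molecular weight (Da) of the peptide."""
    return float(ProteinAnalysis(residues.upper()).molecular_weight())


def concentration(a280: float, epsilon: float, path_cm: float = 1.0,
                  molar_mass_da: float | None = None) -> dict:
    """Beer-Lambert concentration from A280.

    Returns molar concentration; adds mg/mL when a molar mass is given.
    """
    if a280 < 0:
        raise ValueError("A280 must be non-negative")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    if epsilon <= 0:
        raise ValueError(
            "extinction coefficient is zero (no Trp/Tyr/paired Cys): "
            "A280 quantification undefined")
    molar = a280 / (epsilon * path_cm)
    out = {"molar": molar}
    if molar_mass_da is not None:
        out["mg_per_ml"] = molar * molar_mass_da
    return out


# ---------------------------------------------------------------------------
# structure-based disulfide detection

@dataclass(frozen=True)
class AtomRecord:
    residue_name: str
    residue_index: int   # 1-based author numbering
    atom_name: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("non-finite coordinates")


def read_pdb_sg_atoms(path) -> list[AtomRecord]:
    """Cysteine SG atoms from a PDB file (first model, first altloc)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    model = next(iter(structure))
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.get_resname().strip() != "CYS":
                continue
            if "SG" not in res:
                continue
            atom = res["SG"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            x, y, z = atom.get_coord()
            atoms.append(AtomRecord("CYS", res.get_id()[1], "SG",
                                    float(x), float(y), float(z)))
    return atoms


def detect_disulfides(atoms: list[AtomRecord],
                      min_dist: float = 2.0, max_dist: float = 3.0,
                      ) -> list[tuple[int, int]]:
    """Likely disulfide bonds: cysteine pairs with SG-SG distance in
    [min_dist, max_dist] Angstrom, each cysteine in at most one bond
    (greedy by ascending distance).

    Cysteines lacking an SG atom are simply absent from ``atoms`` (the
    reader warns and skips them).  Returns 1-based residue-index pairs,
    each sorted, in ascending-distance order.
    """
    sg = [a for a in atoms if a.atom_name == "SG"]
    cand: list[tuple[float, int, int]] = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = math.dist((sg[i].x, sg[i].y, sg[i].z), (sg[j].x, sg[j].y, sg[j].z))
            if min_dist <= d <= max_dist:
                cand.append((d, sg[i].residue_index, sg[j].residue_index))
    cand.sort()
    used: set[int] = set()
    bonds: list[tuple[int, int]] = []
    for _, r1, r2 in cand:
        if r1 in used or r2 in used:
            continue
        used.update((r1, r2))
        bonds.append(tuple(sorted((r1, r2))))
    return bonds


# ---------------------------------------------------------------------------
# consensus candidate screening

@dataclass(frozen=True)
class ScoreRow:
    id: str
    length: int
    ampir_precursor: float | None = None
    ampir_mature: float | None = None
    multipep_antimicrobial: float | None = None
    multipep_antibacterial: float | None = None
    camp_top_hit: str | None = None
    camp_evalue: float | None = None

    def __post_init__(self) -> None:
        for f in ("ampir_precursor", "ampir_mature",
                  "multipep_antimicrobial", "multipep_antibacterial"):
            v = getattr(self, f)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{f}={v} outside [0, 1]")
        if self.length >= 200 and (self.multipep_antimicrobial is not None
                                   or self.multipep_antibacterial is not None):
            raise ValueError(
                "MultiPep scores present for a sequence >= 200 residues "
                "(outside the tool's input range)")


@dataclass(frozen=True)
class ScreenThresholds:
    ampir: float = 0.7
    multipep: float = 0.7
    camp_evalue: float = 1e-5
    multipep_max_len: int = 200


def screen_candidates(rows: list[ScoreRow],
                      thresholds: ScreenThresholds | None = None) -> pd.DataFrame:
    """Consensus triage: a candidate is retained if any evidence stream
    flags it — ampir (either model) above threshold, MultiPep antimicrobial
    or antibacterial above threshold (length-limited), or a significant
    top CAMP similarity hit."""
    th = thresholds or ScreenThresholds()
    out = []
    for r in rows:
        ampir_flag = any(s is not None and s > th.ampir
                         for s in (r.ampir_precursor, r.ampir_mature))
        multipep_flag = (r.length < th.multipep_max_len and
                         any(s is not None and s > th.multipep
                             for s in (r.multipep_antimicrobial,
                                       r.multipep_antibacterial)))
        camp_flag = r.camp_evalue is not None and r.camp_evalue <= th.camp_evalue
        out.append((r.id, r.length, ampir_flag, multipep_flag, camp_flag,
                    ampir_flag or multipep_flag or camp_flag))
    return pd.DataFrame(out, columns=["id", "length", "ampir_flag",
                                      "multipep_flag", "camp_flag", "retained"])


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path, signal_ranges: dict[str, tuple[int, int]] | None = None,
               ) -> list[PeptideRecord]:
    """Peptides from a FASTA file; optional per-id signal-peptide ranges."""
    signal_ranges = signal_ranges or {}
    recs = []
    for sr in SeqIO.parse(str(path), "fasta"):
        recs.append(PeptideRecord(sr.id, str(sr.seq).upper(),
                                  signal_range=signal_ranges.get(sr.id)))
    return recs


def read_score_table(path) -> list[ScoreRow]:
    """Score rows from a CSV (columns as in :func:`bundled_score_table`)."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            def fval(key):
                v = rec.get(key, "")
                return float(v) if v not in ("", "NA", None) else None
            rows.append(ScoreRow(
                id=rec["id"], length=int(rec["length"]),
                ampir_precursor=fval("ampir_precursor"),
                ampir_mature=fval("ampir_mature"),
                multipep_antimicrobial=fval("multipep_antimicrobial"),
                multipep_antibacterial=fval("multipep_antibacterial"),
                camp_top_hit=rec.get("camp_top_hit") or None,
                camp_evalue=fval("camp_evalue")))
    return rows


def bundled_score_table() -> list[ScoreRow]:
    """The package's bundled predictor-score table for the five shortlisted
    nematode ESP/EV peptides."""
    with resources.as_file(resources.files("wormamp") / "data"
                           / "candidate_scores.csv") as p:
        return read_score_table(p)


def fetch_uniprot_fasta(accession: str, timeout: float = 10.0) -> PeptideRecord:
    """Optional online helper: fetch one sequence from UniProt REST.

    Requires network access; every core operation accepts local FASTA via
    :func:`read_fasta` instead.
    """
    from urllib.request import urlopen

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urlopen(url, timeout=timeout) as fh:  # pragma: no cover - network
        text = fh.read().decode()
    lines = text.strip().splitlines()
    return PeptideRecord(accession, "".join(lines[1:]).upper(),
                         accession=accession)
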