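"""Input/output for enzyme panels and result tables.

An enzyme panel bundles the two experimental inputs of the analysis: a
multiple sequence alignment of mature thioesterase variants (aligned FASTA)
and the fatty-acid product profile each variant produced in vivo (delimited
table, enzymes x fatty-acid species, mol% or concentration).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

#: residue alphabet accepted in alignments: 20 amino acids, gap, unknown
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY-X")


class PanelError(ValueError):
    """Raised when panel inputs violate an invariant."""


@dataclass
class EnzymePanel:
    """Aligned sequences plus fatty-acid profiles, keyed by enzyme id.

    Attributes
    ----------
    enzyme_ids : list of str
        Unique identifiers, in input (FASTA) order.
    alignment : list of str
        One aligned residue string per enzyme, all of equal length ``L``,
        over the 20 amino-acid letters plus ``-`` (gap) and ``X``.
    profiles : pandas.DataFrame
        Non-negative abundance matrix, rows indexed by enzyme id in the
        same order as ``enzyme_ids``, columns labelled by fatty-acid
        species (e.g. ``"8:0"``, ``"14:1"``).
    """

    enzyme_ids: list[str]
    alignment: list[str]
    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views ------------------------------------------------

    @property
    def n_enzymes(self) -> int:
        return len(self.enzyme_ids)

    @property
    def length(self) -> int:
        """Alignment length L."""
        return len(self.alignment[0])

    @property
    def species(self) -> list[str]:
        return list(self.profiles.columns)

    def alignment_matrix(self) -> np.ndarray:
        """Alignment as an (n_enzymes, L) array of single characters."""
        return np.array([list(s) for s in self.alignment])

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if len(self.enzyme_ids) < 3:
            raise PanelError("panel needs at least 3 enzymes")
        if len(set(self.enzyme_ids)) != len(self.enzyme_ids):
            dupes = sorted(
                {e for e in self.enzyme_ids if self.enzyme_ids.count(e) > 1}
            )
            raise PanelError(f"duplicate enzyme ids: {dupes}")
        if len(self.alignment) != len(self.enzyme_ids):
            raise PanelError("alignment row count does not match enzyme ids")
        lengths = {len(s) for s in self.alignment}
        if len(lengths) != 1:
            raise PanelError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        if self.length < 1:
            raise PanelError("alignment length must be >= 1")
        self.alignment = [s.upper() for s in self.alignment]
        for eid, seq in zip(self.enzyme_ids, self.alignment):
            bad = set(seq) - ALPHABET
            if bad:
                raise PanelError(
                    f"sequence {eid!r} contains invalid characters {sorted(bad)}"
                )
        if list(self.profiles.index) != list(self.enzyme_ids):
            raise PanelError("profile row order does not match enzyme ids")
        values = self.profiles.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise PanelError("profile table contains non-numeric values")
        if np.any(~np.isfinite(values)):
            raise PanelError("profile table contains non-finite values")
        if (values < 0).any():
            raise PanelError("negative abundances in profile table")


def _read_fasta(path) -> tuple[list[str], list[str]]:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        # id = header up to first whitespace (SeqIO convention already)
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise PanelError(f"no FASTA records found in {path}")
    return ids, seqs


def _read_profiles(path) -> pd.DataFrame:
    # delimiter auto-detected among comma/tab; first column = enzyme id
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise PanelError(f"non-numeric abundance in {path}: {exc}") from exc
    return df


def read_panel(alignment_path, profiles_path) -> EnzymePanel:
    """Read and cross-validate an aligned FASTA + profile table pair.

    Enzymes present in only one of the two files are an error: the
    mismatching ids are listed so the caller can fix the inputs.
    """
    ids, seqs = _read_fasta(alignment_path)
    profiles = _read_profiles(profiles_path)

    fasta_set, prof_set = set(ids), set(profiles.index)
    only_fasta = sorted(fasta_set - prof_set)
    only_prof = sorted(prof_set - fasta_set)
    if only_fasta or only_prof:
        raise PanelError(
            "enzyme ids do not match between alignment and profiles; "
            f"only in alignment: {only_fasta}; only in profiles: {only_prof}"
        )
    profiles = profiles.loc[ids]  # FASTA record order wins
    return EnzymePanel(enzyme_ids=ids, alignment=seqs, profiles=profiles)


def write_panel(panel: EnzymePanel, alignment_path, profiles_path) -> None:
    """Write a panel back to aligned FASTA + CSV profile table."""
    with open(alignment_path, "w") as fh:
        for eid, seq in zip(panel.enzyme_ids, panel.alignment):
            fh.write(f">{eid}\n{seq}\n")
    panel.profiles.to_csv(profiles_path, float_format="%.12g")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV, round-trippable to ~12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
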