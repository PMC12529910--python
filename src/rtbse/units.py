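"""Unit conversions at the I/O boundary.

All internal arithmetic is carried out in Hartree atomic units
(hbar = e = m_e = 1, 4*pi*eps0 = 1).  Energies cross the boundary in eV
and times in femtoseconds only when reading configuration values or
writing reports.
"""

#: Hartree in electronvolt.
HARTREE_EV = 27.211386

#: Atomic units of time per femtosecond.
AU_TIME_PER_FS = 41.341374


def ev_to_hartree(e_ev: float) -> float:
    return e_ev / HARTREE_EV


def hartree_to_ev(e_ha: float) -> float:
    return e_ha * HARTREE_EV


def fs_to_au(t_fs: float) -> float:
    return t_fs * AU_TIME_PER_FS


def au_to_fs(t_au: float) -> float:
    return t_au / AU_TIME_PER_FS
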