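import numpy as np
import pytest

from pbpkddi.drugs import Absorption, Drug, Inhibition, Pathway
from pbpkddi.engine import DosingRegimen, assemble, simulate
from pbpkddi.network import DrugLibrary
from pbpkddi.physiology import default_individual


@pytest.fixture(scope="session")
def individual():
    return default_individual()


@pytest.fixture(scope="session")
def library():
    return DrugLibrary.builtin()


def make_probe(name="probe", enzyme="CYP1A2", cl_int=0.125, fu=0.5, kp=0.5,
               bp=1.0, ka=0.03, f_abs=1.0, inhibitions=(), **extra):
    """Single-linear-pathway drug with round-number illustrative PK
    (fu·CLint·E ≈ 0.1 L/min with the reference liver, low extraction)."""
    return Drug(name=name, molecular_weight=250.0, fu=fu,
                blood_plasma_ratio=bp, kp_map={"default": kp},
                pathways=[Pathway(enzyme=enzyme, kinetics="linear",
                                  cl_int=cl_int)],
                inhibitions=list(inhibitions),
                absorption={"oral": Absorption(ka=ka, f_abs=f_abs)},
                **extra)


@pytest.fixture(scope="session")
def probe():
    return make_probe()


@pytest.fixture(scope="session")
def autoinhibitor():
    """Linear CYP2C19 victim carrying a mild self-inactivation (TDI), the
    moclobemide/omeprazole autoinhibition structure."""
    return make_probe(name="auto", enzyme="CYP2C19", cl_int=0.222,
                      inhibitions=[Inhibition(target_enzyme="CYP2C19",
                                              mechanism="tdi",
                                              k_i_tdi=20.0, k_inact=0.003)])


def iv(drug, dose, times=(0.0,)):
    return DosingRegimen(drug=drug, route="iv_bolus", dose=dose,
                         times=list(times))


def oral(drug, dose, times=(0.0,)):
    return DosingRegimen(drug=drug, route="oral", dose=dose,
                         times=list(times))


def run(ind, drugs, regimens, t_end, n=1201, **assemble_kw):
    sys = assemble(ind, drugs, regimens, **assemble_kw)
    return simulate(sys, t_end, np.linspace(0.0, t_end, n))
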