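import textwrap

import pytest

from isrscape import DecoyEnsemble, PanelConfig, VariantRecord, simulate_panel

# Hand-built AutoDock4 DLG excerpt: three docked runs whose final
# "Estimated Free Energy of Binding" lines read -7.12, -6.30, -6.95 kcal/mol,
# interleaved with non-DOCKED log noise a real DLG contains.
DLG_TEXT = textwrap.dedent(
    """\
    AutoDock 4.2 Release

    DPF> move ligand.pdbqt
    Run: 1 / 3
    DOCKED: MODEL        1
    DOCKED: USER    Run = 1
    DOCKED: USER    Estimated Free Energy of Binding    =   -7.12 kcal/mol  [=(1)+(2)+(3)-(4)]
    DOCKED: USER    Estimated Inhibition Constant, Ki   =   6.07 uM
    DOCKED: ENDMDL
    Run: 2 / 3
    Ping-pong swap of state variables.
    DOCKED: MODEL        2
    DOCKED: USER    Run = 2
    DOCKED: USER    Estimated Free Energy of Binding    =   -6.30 kcal/mol  [=(1)+(2)+(3)-(4)]
    DOCKED: ENDMDL
    Run: 3 / 3
    DOCKED: MODEL        3
    DOCKED: USER    Run = 3
    DOCKED: USER    Estimated Free Energy of Binding    =   -6.95 kcal/mol  [=(1)+(2)+(3)-(4)]
    DOCKED: ENDMDL
    Successful Completion
    """
)


@pytest.fixture
def dlg_text():
    return DLG_TEXT


@pytest.fixture
def hand_ensemble():
    """The worked example: En=-10, decoy mean -5, gap 5, sd sqrt(2/3)."""
    return DecoyEnsemble("hand", [-10.0, -5.0, -4.0, -6.0, -5.0])


@pytest.fixture
def small_panel():
    """Four fully populated variant records with one wild type."""
    return [
        VariantRecord("WT", isr=5.0, binding_affinity=-8.0, reaction_barrier=20.0,
                      ln_activity=-20.0, is_wild_type=True),
        VariantRecord("W83A", isr=3.503, binding_affinity=-7.0,
                      reaction_barrier=21.0, ln_activity=-23.0),
        VariantRecord("W164A", isr=2.985, binding_affinity=-6.5,
                      reaction_barrier=22.0, ln_activity=-25.0),
        VariantRecord("F208A", isr=3.827, binding_affinity=-7.2,
                      reaction_barrier=20.5, ln_activity=-22.0),
    ]


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel, shared across tests that only read it."""
    return simulate_panel(PanelConfig(seed=1))
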