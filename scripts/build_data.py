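"""Regenerate the shipped data files under src/tfx/data/.

The anchor alignment, calibration table and registry file are derived from
the layout/template/criteria tables in the package source; this script
renders them to disk so that the shipped artefacts and the code cannot
drift apart.  Run from the repository root:

    python scripts/build_data.py
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tfx.templates import (anchor_sequences, exemplar_gapped, gapped,
                           EXEMPLAR_LAYOUTS)
from tfx.calibration import CALIBRATION_PAIRS, SOFT_PAIRS

DATA = Path(__file__).resolve().parents[1] / "src" / "tfx" / "data"


def write_anchors():
    lines = []
    for name, (family, seq, lay) in anchor_sequences().items():
        lines.append(f">{name} family={family} kind=anchor synthetic=1")
        lines.append(gapped(lay, seq))
    for name, lay in EXEMPLAR_LAYOUTS.items():
        lines.append(f">{name} family={lay.family} kind=exemplar synthetic=1")
        lines.append(exemplar_gapped(name, lay, lay.family))
    (DATA / "anchors.afa").write_text("\n".join(lines) + "\n")


def write_calibration():
    rows = ["toxin_id\toriginal_pos\texpected_column\tstatus\tnote"]
    for toxin, pos, col, note in CALIBRATION_PAIRS:
        rows.append(f"{toxin}\t{pos}\t{col}\thard\t{note}")
    for toxin, pos, col, note in SOFT_PAIRS:
        rows.append(f"{toxin}\t{pos}\t{col}\tsoft\t{note}")
    (DATA / "calibration.tsv").write_text("\n".join(rows) + "\n")


def write_registry():
    from tfx.criteria import render_registry_tsv
    (DATA / "registry.tsv").write_text(render_registry_tsv())


def write_site_tables():
    from tfx.features import (render_dimer_models_tsv,
                              render_functional_sites_tsv)
    (DATA / "functional_sites.tsv").write_text(render_functional_sites_tsv())
    (DATA / "dimer_models.tsv").write_text(render_dimer_models_tsv())


if __name__ == "__main__":
    write_anchors()
    write_calibration()
    write_registry()
    write_site_tables()
    print("data files written to", DATA)
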