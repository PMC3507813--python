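"""ramaquery: scriptable dihedral-space queries on small peptide structural elements.

The package extracts contiguous n-mers (2-9 residues) from protein
chains, computes backbone and first side-chain dihedrals, classifies
Ramachandran regions and proline pucker, and supports reproducible
selection workflows: dihedral templates, sequence patterns, and
rectangular/elliptical marquee queries in shiftable periodic axis
windows — with text-format export, summary statistics and static plots.
"""

from importlib import resources

from .structure_io import (
    AtomRecord,
    ChainModel,
    EmptyStructureError,
    ResidueRecord,
    one_letter,
    read_pdb,
)
from .geometry import (
    CHI1_GAMMA_ATOM,
    ResidueConformation,
    circular_difference,
    normalize_angle,
    residue_dihedrals,
    torsion,
)
from .fixtures import BackboneSpec, build_backbone, write_pdb
from .conformation import (
    DEFAULT_REGIONS,
    RegionDef,
    classify_pucker,
    classify_region,
    read_regions,
)
from .elements import (
    DEFAULT_TOL,
    AngleTemplate,
    ElementSet,
    SequencePattern,
    StructuralElement,
    composition,
    extract_nmers,
    filter_pattern,
    match_template,
    read_template,
)
from .selection import AxisWindow, Marquee, highlight_mode, remap, select_marquee
from .stats import (
    SelectionStats,
    anti_pairs,
    circular_mean,
    selection_stats,
    superimpose_positions,
)
from .io_format import FormatError, read_elements, write_elements, write_listing
from .plotting import plot_elements, plot_superimposed

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a shipped data file (region table, example turn templates)."""
    return resources.files(__package__) / "data" / name
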