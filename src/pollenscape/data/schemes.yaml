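# The nine published tree-pollen allergenicity classification schemes and
# their mapping onto the common severity scale (high / moderate / low).
# Entry files (taxon,label) are user-supplied; several sources are
# proprietary or web resources and are not redistributed here.

AAAAI:
  kind: categorical
  description: American Academy of Allergy, Asthma & Immunology plant guidance
  region: United States
  labels:
    high: ["Highly allergenic plants", "Highly allergenic"]
    moderate: ["Allergenic plants", "Allergenic"]
    low: ["Low-allergenic plants", "Low-allergenic"]

AIA:
  kind: categorical
  description: Italian Association of Aerobiology systematic review (planting recommendations)
  region: Italy
  labels:
    high: ["Species whose planting should be avoided"]
    moderate: ["Species whose planting should be limited and/or avoided in certain locations"]
    low: ["Species whose planting has no restrictions"]

ARL:
  kind: categorical
  description: Aerobiology Research Laboratories pollen taxa descriptions
  region: Canada
  labels:
    high: ["Highly allergenic"]
    moderate: ["Moderately allergenic"]
    low: ["In high enough numbers may cause allergic reactions"]

Citree:
  kind: categorical
  description: Citree urban tree selection database
  region: Europe
  labels:
    high: ["High allergy potential"]
    moderate: ["Medium allergy potential"]
    low: ["Low allergy potential"]

EAN:
  kind: categorical
  description: European Aeroallergen Network allergenic plant profiles
  region: Europe
  labels:
    high: ["High allergenicity", "High"]
    moderate: ["Moderate allergenicity", "Moderate"]
    low: ["Low allergenicity", "Low"]

INSPQ:
  kind: categorical
  description: Quebec Institute of Public Health allergenic plant shortlist (star ratings)
  region: Quebec, Canada
  labels:
    high: ["***", "high"]
    moderate: ["**", "medium"]
    low: ["*", "low"]

OPALS:
  kind: numeric
  description: Ogren Plant Allergy Scale, 1 (least) to 10 (most allergenic)
  region: United States
  breakpoints:
    high: [7, 10]
    moderate: [4, 6]
    low: [1, 3]

Pollen.com:
  kind: categorical
  description: Pollen.com (IQVIA) plant allergy library
  region: United States
  labels:
    high: ["Severe allergenicity", "Severe"]
    moderate: ["Moderate allergenicity", "Moderate"]
    low: ["Mild allergenicity", "Mild"]

RNSA:
  kind: categorical
  description: French aerobiological monitoring network vegetation guide
  region: France
  labels:
    high: ["Strong allergy potential", "Strong"]
    moderate: ["Medium allergy potential", "Moderate allergy potential", "Medium", "Moderate"]
    low: ["Low allergy potential", "Non-allergenic species", "Low", "Non-allergenic"]
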