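{
  "_comment": "Reconstructed default remap from ADE20K 150-class scene-parsing indices to the 11 park landscape features. The original study did not publish its mapping; override with your own CSV/JSON for real analyses. Classes not listed (person, vehicles, indoor furniture, ...) fall to 'other'.",
  "2": "sky",
  "21": "water",
  "26": "water",
  "60": "water",
  "104": "water",
  "109": "water",
  "113": "water",
  "128": "water",
  "4": "tree",
  "72": "tree",
  "17": "shrub",
  "66": "shrub",
  "9": "grass",
  "29": "grass",
  "1": "building",
  "25": "building",
  "48": "building",
  "79": "building",
  "84": "building",
  "6": "pavement",
  "11": "pavement",
  "52": "pavement",
  "121": "pavement",
  "13": "rough_ground",
  "16": "rough_ground",
  "34": "rough_ground",
  "46": "rough_ground",
  "68": "rough_ground",
  "91": "rough_ground",
  "94": "rough_ground",
  "19": "resting_facility",
  "31": "resting_facility",
  "69": "resting_facility",
  "110": "resting_facility",
  "43": "service_facility",
  "77": "service_facility",
  "88": "service_facility",
  "138": "service_facility",
  "144": "service_facility",
  "86": "shading_facility",
  "106": "shading_facility"
}
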