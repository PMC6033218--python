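{
 "note": "SYNTHETIC example centroids for the two-class nearest-centroid classifier; schema demonstration only. The published ccA/ccB centroid values are supplied by the user as config.",
 "method": "pearson",
 "centroids": {
  "ccA": {
   "CC01": -0.0399,
   "CC02": -1.2577,
   "CC03": 2.574,
   "CC04": 0.4818,
   "CC05": 0.6435,
   "CC06": -0.2079,
   "CC07": 0.0583,
   "CC08": 0.3367,
   "CC09": 0.1951,
   "CC10": -0.6093,
   "CC11": 0.6147,
   "CC12": 0.4904,
   "CC13": -0.1183,
   "CC14": -0.7192,
   "CC15": -0.8794,
   "CC16": -1.008,
   "CC17": 0.2766,
   "CC18": -0.3509,
   "CC19": 0.8711,
   "CC20": -0.8878,
   "CC21": 0.7258,
   "CC22": 0.0269,
   "CC23": -0.5689,
   "CC24": 1.0446,
   "CC25": 0.1507,
   "CC26": 0.7902,
   "CC27": 1.0911,
   "CC28": 0.4945,
   "CC29": -0.4872,
   "CC30": 0.1858,
   "CC31": 1.0045,
   "CC32": -0.6234,
   "CC33": 0.5457,
   "CC34": -0.1957
  },
  "ccB": {
   "CC01": -0.201,
   "CC02": 0.9768,
   "CC03": -3.1146,
   "CC04": -0.6142,
   "CC05": -0.454,
   "CC06": -0.7806,
   "CC07": -0.2583,
   "CC08": -0.233,
   "CC09": -0.3939,
   "CC10": 0.978,
   "CC11": -1.0201,
   "CC12": -0.1406,
   "CC13": 0.5138,
   "CC14": 0.9064,
   "CC15": 0.5038,
   "CC16": 1.8759,
   "CC17": -0.4092,
   "CC18": 0.5947,
   "CC19": -1.3652,
   "CC20": 0.5267,
   "CC21": -0.5442,
   "CC22": -0.7272,
   "CC23": 0.7778,
   "CC24": -0.1902,
   "CC25": -0.8655,
   "CC26": -0.9467,
   "CC27": -0.6847,
   "CC28": -0.6831,
   "CC29": 0.8802,
   "CC30": -0.1161,
   "CC31": -1.8535,
   "CC32": -0.6768,
   "CC33": -0.6904,
   "CC34": 0.6297
  }
 }
}
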