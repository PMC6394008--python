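{"patient_id":"P00000","date":"2011-06-16","consultation_type":"administrative","events":[{"category":"reason_for_encounter_icpc","code":"P84.03"}],"labs":[],"medications":[],"documents":[{"doc_type":"letter","text":"Geachte collega,\nlopen verwijzing bloeddruk medicatie vallen uitslag thuis vallen eetlust pijn conditie bloeddruk klachten lopen stabiel huisarts zorg recept bloeddruk gesprek lopen\nMet vriendelijke groet, huisarts"}]}
{"patient_id":"P00000","date":"2011-10-14","consultation_type":"home_visit","events":[{"category":"icd","code":"N15.04"},{"category":"intervention_icpc","code":"U15.04"}],"labs":[],"medications":[],"documents":[{"doc_type":"note","text":"medicatie familie overleg thuis verwijzing slapen afspraak huisarts gesprek eetlust benauwd benauwd onderzoek onderzoek vallen klachten"}]}
{"patient_id":"P00000","date":"2012-01-03","consultation_type":"administrative","events":[{"category":"medical_history_icpc","code":"D84.01"}],"labs":[],"medications":[],"documents":[{"doc_type":"note","text":"klachten eetlust stabiel vallen recept familie stabiel uitslag patient telefonisch thuis afspraak telefonisch geheugen onderzoek familie lopen controle lopen recept patient thuis stabiel"}]}
{"patient_id":"P00000","date":"2013-01-17","consultation_type":"visit","events":[{"category":"intervention_icpc","code":"U84.04"},{"category":"reason_for_encounter_icpc","code":"P73.03"}],"labs":[{"lab_code":"K","value":"136","flag":"irregular"}],"medications":["omeprazol 20mg","paracetamol 500mg 3dd","simvastatine 40mg 1dd1"],"documents":[]}
{"patient_id":"P00000","date":"2013-02-05","consultation_type":"visit","events":[{"category":"reason_for_encounter_icpc","code":"A11.00"},{"category":"medical_history_icpc","code":"A84.00"}],"labs":[],"medications":[],"documents":[{"doc_type":"note","text":"vallen besproken overleg controle medicatie slapen conditie conditie stabiel besproken afspraak thuis thuis eetlust"}]}
{"patient_id":"P00000","date":"2013-10-22","consultation_type":"phone","events":[{"category":"diagnosis_icpc","code":"D84.00"},{"category":"intervention_icpc","code":"L72.02"},{"category":"reason_for_encounter_icpc","code":"S74.04"}],"labs":[],"medications":["metoprolol 50mg 1dd"],"documents":[{"doc_type":"letter","text":"Geachte collega,\nmoe bloeddruk conditie besproken afspraak klachten lopen onderzoek recept pijn klachten pijn controle gewicht verwijzing slapen lopen lopen stabiel verwijzing conditie eetlust\nMet vriendelijke groet, huisarts"}]}
{"patient_id":"P00000","date":"2014-04-09","consultation_type":"home_visit","events":[{"category":"intervention_icpc","code":"D70.00"}],"labs":[],"medications":[],"documents":[{"doc_type":"note","text":"pijn besproken geheugen familie verwijzing slapen thuis conditie thuis vervolg recept lopen geheugen gesprek uitslag klachten"}]}
{"patient_id":"P00000","date":"2014-05-15","consultation_type":"home_visit","events":[{"category":"icd","code":"N74.04"}],"labs":[],"medications":[],"documents":[{"doc_type":"note","text":"recept patient uitslag besproken gewicht recept pijn onderzoek pijn stabiel lopen klachten gewicht"}]}
{"patient_id":"P00000","date":"2014-07-19","consultation_type":"home_visit","events":[],"labs":[{"lab_code":"CREA","value":"150","flag":"abnormal"}],"medications":[],"documents":[{"doc_type":"note","text":"familie afspraak stabiel thuis gesprek familie pijn onderzoek eetlust gesprek thuis uitslag geheugen gesprek controle"}]}
{"patient_id":"P00000","date":"2015-01-12","consultation_type":"administrative","events":[{"category":"diagnosis_icpc","code":"R72.02"},{"category":"diagnosis_icpc","code":"L73.03"}],"labs":[],"medications":["omeprazol 20mg"],"documents":[]}
{"patient_id":"P00000","date":"2015-02-08","consultation_type":"home_visit","events":[{"category":"intervention_icpc","code":"D84.00"}],"labs":[{"lab_code":"CREA","value":"25","flag":"normal"}],"medications":[],"documents":[{"doc_type":"letter","text":"Geachte collega,\nhuisarts benauwd stabiel zorg pijn eetlust eetlust pijn thuis medicatie bloeddruk overleg moe patient uitslag controle besproken conditie\nMet vriendelijke groet, huisarts"}]}
{"patient_id":"P00000","date":"2015-07-23","consultation_type":"home_visit","events":[{"category":"medical_history_icpc","code":"T84.04"}],"labs":[],"medications":[],"documents":[{"doc_type":"letter","text":"Geachte collega,\nbesproken lopen stabiel bloeddruk conditie uitslag slapen verwijzing vallen medicatie gesprek geheugen slapen geheugen besproken geheugen controle gewicht huisarts klachten overleg\nMet vriendelijke groet, huisarts"}]}
{"patient_id":"P00000","date":"2015-08-21","consultation_type":"visit","events":[{"category":"medical_history_icpc","code":"A84.00"},{"category":"reason_for_encounter_icpc","code":"P84.03"},{"category":"intervention_icpc","code":"D11.00"}],"labs":[{"lab_code":"HB","value":"84","flag":"normal"}],"medications":[],"documents":[{"doc_type":"note","text":"slapen verwijzing zorg afspraak afspraak zorg zorg zorg afspraak lopen gewicht pijn slapen huisarts telefonisch vallen geheugen vallen eetlust thuis bloeddruk gewicht gewicht"}]}
{"patient_id":"P00000","date":"2015-10-08","consultation_type":"home_visit","events":[{"category":"diagnosis_icpc","code":"L73.03"}],"labs":[],"medications":[],"documents":[{"doc_type":"letter","text":"Geachte collega,\ngesprek besproken besproken besproken vallen stabiel lopen geheugen slapen moe klachten benauwd vallen moe telefonisch\nMet vriendelijke groet, huisarts"}]}
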