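family,species,individuals,groups,transects,coral_associated_adult,algal_adult
Acanthuridae,Acanthurus grammoptilus,40,26,18,0,0
Acanthuridae,Acanthurus dussumieri,12,7,4,0,0
Apogonidae,Apogon rueppellii,128,18,8,0,1
Apogonidae,Apogon wassinki,332,22,20,0,0
Apogonidae,Cheilodipterus quinquelineatus,20,18,11,0,0
Blenniidae,Atrosalarias fuscus,13,10,8,0,0
Chaetodontidae,Chaetodon assarius,24,21,17,0,0
Chaetodontidae,Chaetodon auriga,6,6,5,0,0
Chaetodontidae,Chaetodon plebeius,116,95,55,1,0
Chaetodontidae,Chaetodon trifascialis,14,14,12,1,0
Chaetodontidae,Chaetodon trifasciatus,7,6,5,1,0
Labridae,Anampses geographicus,234,42,27,0,0
Labridae,Anampses caeruleopunctatus,11,9,9,0,0
Labridae,Coris aygula,6,4,4,0,0
Labridae,Coris caudimacula,158,66,37,0,0
Labridae,Cheilinus chlorourus,17,14,8,0,0
Labridae,Cheilinus trilobatus,59,56,33,0,0
Labridae,Cheilio inermis,20,10,8,0,0
Labridae,Gomphosus varius,12,12,11,0,0
Labridae,Hologymnosus annulatus,9,8,7,0,0
Labridae,Halichoeres marginatus,11,11,8,0,0
Labridae,Halichoeres nebulosus,203,132,38,0,1
Labridae,Hemigymnus fasciatus,8,7,7,0,0
Labridae,Hemigymnus melapterus,33,32,23,0,0
Labridae,Labrichthys unilineatus,155,97,51,1,0
Labridae,Labroides dimidiatus,18,16,13,0,0
Labridae,Macropharyngodon ornatus,35,33,23,0,0
Labridae,Stethojulis bandanensis,442,314,106,0,0
Labridae,Stethojulis interrupta,431,230,79,0,0
Labridae,Stethojulis strigiventer,219,92,42,0,0
Labridae,Thalassoma hardwicke,33,31,20,0,0
Labridae,Thalassoma lunare,354,243,95,0,0
Labridae,Thalassoma lutescens,26,25,16,0,0
Lethrinidae,Lethrinus atkinsoni,105,66,22,0,0
Monocanthidae,Oxymonacanthus longirostris,7,4,4,1,0
Mullidae,Parupeneus barberinoides,47,28,18,0,0
Mullidae,Parupeneus spilurus,149,49,32,0,0
Nemipteridae,Scolopsis bilineatus,7,7,6,0,0
Pomacentridae,Chromis viridis,447,29,22,1,0
Pomacentridae,Dascyllus aruanus,213,101,52,1,0
Pomacentridae,Dascyllus reticulatus,109,47,30,1,0
Pomacentridae,Dascyllus trimaculatus,21,8,8,1,0
Pomacentridae,Dischistodus perspicillatus,5,4,4,0,0
Pomacentridae,Dischistodus prosopotaenia,8,8,4,0,0
Pomacentridae,Neoglyphidodon melas,26,20,14,0,0
Pomacentridae,Pomacentrus coelestis,748,182,69,0,0
Pomacentridae,Pomacentrus moluccensis,632,324,94,1,0
Pomacentridae,Pomacentrus vaiuli,60,59,29,0,0
Pomacentridae,Plectroglyphidodon lacrymatus,55,51,37,0,0
Pomacentridae,Stegastes nigricans,10,8,6,0,0
Pomacentridae,Stegastes obreptus,10,10,9,0,0
Scaridae,Chlorurus microrhinos,26,22,18,0,0
Scaridae,Chlorurus sordidus,516,226,85,0,0
Scaridae,Leptoscarus vaigiensis,410,91,40,0,1
Scaridae,Scarus frenatus,71,49,35,0,0
Scaridae,Scarus prasiognathos,91,68,44,0,0
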